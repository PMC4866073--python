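"""Median-joining haplotype networks.

The network is built over coded haplotype vectors (substitution states
plus binary indel and structural states), all characters equally
weighted so that every branch segment is one mutation step —
substitution steps and indel steps are labelled separately so a plot
can draw them as full versus double lines.

Algorithm (Bandelt, Forster & Roehl): iterate { build the
epsilon-relaxed minimum spanning network over the current node set;
for every connected triplet add its quasi-median (majority state per
character, with all resolutions enumerated when no majority exists) }
until no new median arises; finally remove median vectors that do not
lie on any shortest path between observed haplotypes.  Links discovered
at any stage are retained, so the final graph records all equally
parsimonious alternative connections (at epsilon = 0 it contains a
minimum spanning tree of the observed haplotypes).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .haplotyping import MISSING, HaplotypeSet
from .io_formats import DataError, SpecimenTable

#: hard cap on inferred median vectors (quasi-median enumeration can
#: explode on very diverse multistate data)
MEDIAN_CAP = 10_000


@dataclass
class NetworkNode:
    node_id: str
    vector: tuple[str, ...]
    is_median: bool
    members: list[str]
    species: frozenset[str]


@dataclass
class MJNetwork:
    nodes: list[NetworkNode]
    edges: list[tuple[str, str, int, tuple[str, ...]]]  # (a, b, n_steps, step kinds)
    character_kinds: tuple[str, ...]

    def node(self, node_id: str) -> NetworkNode:
        return next(n for n in self.nodes if n.node_id == node_id)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.node_id,
                is_median=n.is_median,
                n_members=len(n.members),
                species=",".join(sorted(n.species)),
            )
        for a, b, w, kinds in self.edges:
            g.add_edge(a, b, weight=w, steps=",".join(kinds))
        return g

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _, _ in self.edges}

    def vectors(self) -> dict[str, tuple[str, ...]]:
        return {n.node_id: n.vector for n in self.nodes}


def _missing_mask(kinds: Sequence[str]):
    """Per-character set of tokens treated as missing for step counting."""
    return [
        frozenset({MISSING, "N", "-"}) if k == "sub" else frozenset({MISSING})
        for k in kinds
    ]


class _StepCounter:
    def __init__(self, kinds: Sequence[str]):
        self.kinds = list(kinds)
        self.missing = _missing_mask(kinds)

    def steps(self, a: tuple[str, ...], b: tuple[str, ...]) -> int:
        return sum(
            1
            for x, y, miss in zip(a, b, self.missing)
            if x != y and x not in miss and y not in miss
        )

    def step_kinds(self, a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(
            k
            for x, y, miss, k in zip(a, b, self.missing, self.kinds)
            if x != y and x not in miss and y not in miss
        )

    def quasi_medians(
        self,
        u: tuple[str, ...],
        v: tuple[str, ...],
        w: tuple[str, ...],
    ) -> list[tuple[str, ...]]:
        """Majority consensus per character; all resolutions on full ties."""
        options: list[list[str]] = []
        for x, y, z, miss in zip(u, v, w, self.missing):
            cand = [s for s in (x, y, z) if s not in miss]
            if not cand:
                options.append([MISSING])
                continue
            counts = Counter(cand)
            state, top = counts.most_common(1)[0]
            if top >= 2:
                options.append([state])
            else:
                options.append(sorted(counts))
        return [tuple(p) for p in itertools.product(*options)]


def _msn_edges(
    nodes: Sequence[tuple[str, ...]], counter: _StepCounter, epsilon: int
) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum spanning network over vectors.

    An edge of weight w joins u and v iff their components are distinct
    in the graph formed by all retained edges of weight < w - epsilon.
    """
    n = len(nodes)
    pairs = [
        (counter.steps(nodes[i], nodes[j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    ]
    by_weight: dict[int, list[tuple[int, int]]] = {}
    for w, i, j in pairs:
        by_weight.setdefault(w, []).append((i, j))

    included: list[tuple[int, int, int]] = []  # (i, j, w)

    def components(limit: int) -> list[int]:
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j, w in included:
            if w < limit:
                parent[find(i)] = find(j)
        return [find(x) for x in range(n)]

    for w in sorted(by_weight):
        comp = components(w - epsilon)
        if len(set(comp)) == 1:
            break
        for i, j in by_weight[w]:
            if comp[i] != comp[j]:
                included.append((i, j, w))
    return included


def mj_network(
    hs: HaplotypeSet, epsilon: int = 0, median_cap: int = MEDIAN_CAP
) -> MJNetwork:
    """Median-joining network over the haplotypes of one combination."""
    if not hs.haplotypes:
        raise DataError("no haplotypes to network")
    lengths = {len(h.vector) for h in hs.haplotypes}
    if len(lengths) > 1:
        raise DataError("haplotype vectors have non-uniform lengths")
    counter = _StepCounter(hs.character_kinds or ("sub",) * lengths.pop())

    observed = {h.vector: h for h in hs.haplotypes}
    medians: set[tuple[str, ...]] = set()
    all_edges: dict[frozenset[tuple[str, ...]], int] = {}

    while True:
        current = list(observed) + sorted(medians)
        for i, j, w in _msn_edges(current, counter, epsilon):
            all_edges[frozenset((current[i], current[j]))] = w
        # the spanning network connects every triplet of nodes, so the
        # quasi-median step runs over all triplets of the current set
        new: set[tuple[str, ...]] = set()
        for trip in itertools.combinations(current, 3):
            for qm in counter.quasi_medians(*trip):
                if qm not in observed and qm not in medians:
                    new.add(qm)
            if len(medians) + len(new) > median_cap:
                raise DataError(
                    f"median generation exceeded {median_cap} nodes; the data "
                    "are too diverse for exhaustive quasi-median enumeration — "
                    "consider star-contraction preprocessing"
                )
        if not new:
            break
        medians |= new

    # prune medians not on any shortest path between observed haplotypes
    g = nx.Graph()
    g.add_nodes_from(list(observed) + sorted(medians))
    for e, w in all_edges.items():
        a, b = tuple(e)
        if a in g and b in g:
            g.add_edge(a, b, weight=w)
    spd = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    obs_list = list(observed)
    kept_medians = []
    for m in sorted(medians):
        on_path = any(
            spd[a].get(m, float("inf")) + spd[m].get(b, float("inf"))
            == spd[a].get(b, float("inf"))
            for a, b in itertools.combinations(obs_list, 2)
        )
        if on_path:
            kept_medians.append(m)

    final_vectors = list(observed) + kept_medians
    final_set = set(final_vectors)

    nodes = []
    ids: dict[tuple[str, ...], str] = {}
    for vec in observed:
        h = observed[vec]
        ids[vec] = h.label
        nodes.append(NetworkNode(h.label, vec, False, list(h.members), h.species))
    for k, vec in enumerate(kept_medians, start=1):
        ids[vec] = f"mv{k}"
        nodes.append(NetworkNode(f"mv{k}", vec, True, [], frozenset()))

    edges = []
    for e, w in sorted(all_edges.items(), key=lambda kv: sorted(ids.get(v, "") for v in kv[0])):
        a, b = tuple(e)
        if a in final_set and b in final_set:
            edges.append((ids[a], ids[b], w, counter.step_kinds(a, b)))

    net = MJNetwork(nodes=nodes, edges=edges, character_kinds=tuple(counter.kinds))
    if len(net.nodes) > 1 and not nx.is_connected(net.graph()):
        raise AssertionError("median-joining network is not connected")
    return net


def network_summary(net: MJNetwork, specimens: SpecimenTable) -> dict:
    """Haplotype-sharing statistics.

    Reports, per haplotype, its species composition; per species, the
    percentage of its specimens sitting on private versus shared nodes;
    and per genus, the percentage of species involved in any sharing.
    """
    observed = [n for n in net.nodes if not n.is_median]
    species_total: Counter = Counter()
    species_private: Counter = Counter()
    sharing_species: set[str] = set()
    per_haplotype = {}
    for n in observed:
        per_haplotype[n.node_id] = {
            "n_members": len(n.members),
            "species": sorted(n.species),
            "private": len(n.species) == 1,
        }
        if len(n.species) > 1:
            sharing_species.update(n.species)
        for sid in n.members:
            sp = specimens.species_of(sid)
            species_total[sp] += 1
            if len(n.species) == 1:
                species_private[sp] += 1

    all_species = sorted(species_total)
    per_species = {
        sp: {
            "n_specimens": species_total[sp],
            "percent_private": 100.0 * species_private[sp] / species_total[sp],
            "percent_shared": 100.0 * (species_total[sp] - species_private[sp])
            / species_total[sp],
        }
        for sp in all_species
    }
    n_total = sum(species_total.values())
    n_private = sum(species_private.values())
    return {
        "per_haplotype": per_haplotype,
        "per_species": per_species,
        "percent_specimens_private": 100.0 * n_private / n_total if n_total else None,
        "percent_species_sharing": (
            100.0 * len(sharing_species) / len(all_species) if all_species else None
        ),
        "n_median_nodes": sum(1 for n in net.nodes if n.is_median),
    }


def write_network_tsv(net: MJNetwork, nodes_path: str | Path, edges_path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "node_id": n.node_id,
                "is_median": int(n.is_median),
                "n_members": len(n.members),
                "members": ";".join(n.members),
                "species": ";".join(sorted(n.species)),
            }
            for n in net.nodes
        ]
    ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"node_a": a, "node_b": b, "n_steps": w, "step_kinds": ";".join(kinds)}
            for a, b, w, kinds in net.edges
        ]
    ).to_csv(edges_path, sep="\t", index=False)


def write_graphml(net: MJNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph(), str(path))


def plot_network(net: MJNetwork, path: str | Path, seed: int = 0) -> None:
    """Static network plot; circle size proportional to member count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = net.graph()
    pos = nx.spring_layout(g, seed=seed, weight=None)
    sizes = [40 + 60 * g.nodes[n]["n_members"] for n in g]
    colors = ["0.4" if g.nodes[n]["is_median"] else "tab:blue" for n in g]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, node_color=colors,
                     with_labels=True, font_size=6)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
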