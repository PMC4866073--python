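"""Independent oracles and small builders shared across tests.

Everything in here is deliberately written by a different route than the
library code it checks: interval inspection instead of run extraction
for indel coding, exhaustive subset enumeration for rarefaction,
path-length matrices from an explicitly built tree for NJ, and the full
quasi-median closure for median-joining networks.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx

from barcodegap.haplotyping import Haplotype, HaplotypeSet
from barcodegap.io_formats import SpecimenRecord, SpecimenTable


# ---------------------------------------------------------------------------
# simple indel coding oracle: score every candidate interval by direct
# character inspection of each row
# ---------------------------------------------------------------------------

def sic_oracle(rows: list[str]) -> dict[tuple[int, int], list[str]]:
    """Map each indel character (start, end) to per-row states 1/0/?."""
    length = len(rows[0])

    def state(row: str, s: int, e: int) -> str:
        if "-" not in row[s : e + 1].replace("-", "") and all(
            c == "-" for c in row[s : e + 1]
        ):
            left_open = s > 0 and row[s - 1] == "-"
            right_open = e < length - 1 and row[e + 1] == "-"
            if not left_open and not right_open:
                return "1"  # exactly this maximal run
            return "?"  # swallowed by a longer gap
        return "0"

    chars = {}
    for s in range(length):
        for e in range(s, length):
            states = [state(row, s, e) for row in rows]
            if "1" not in states:
                continue  # nobody carries exactly this run
            if all(st == "1" for st in states):
                continue  # invariant gap, no variation
            chars[(s, e)] = states
    return chars


# ---------------------------------------------------------------------------
# rarefaction oracle: average distinct haplotypes over every subset
# ---------------------------------------------------------------------------

def rarefaction_oracle(frequencies: list[int], g: int) -> float:
    pool = [k for k, nk in enumerate(frequencies) for _ in range(nk)]
    subsets = list(itertools.combinations(range(len(pool)), g))
    total = sum(len({pool[i] for i in subset}) for subset in subsets)
    return total / len(subsets)


# ---------------------------------------------------------------------------
# random additive trees for NJ consistency
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_leaves: int):
    """A random binary tree; returns (labels, D, true bipartitions)."""
    g = nx.Graph()
    labels = [f"t{i}" for i in range(n_leaves)]
    g.add_edge(labels[0], "c")
    g.add_edge(labels[1], "c")
    g.add_edge(labels[2], "c")
    next_internal = 0
    for leaf in labels[3:]:
        u, v = list(g.edges)[rng.integers(g.number_of_edges())]
        mid = f"i{next_internal}"
        next_internal += 1
        g.remove_edge(u, v)
        g.add_edge(u, mid)
        g.add_edge(mid, v)
        g.add_edge(leaf, mid)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(0.05, 0.5))

    spd = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    import numpy as np

    D = np.array([[spd[a][b] for b in labels] for a in labels])

    ref = min(labels)
    bips = set()
    for u, v in list(g.edges):
        w = g.edges[u, v]["weight"]
        g.remove_edge(u, v)
        side = {x for x in nx.node_connected_component(g, u) if x in labels}
        g.add_edge(u, v, weight=w)
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= n_leaves - 2:
            bips.add(frozenset(side))
    return labels, D, bips


# ---------------------------------------------------------------------------
# quasi-median closure oracle for MJ networks
# ---------------------------------------------------------------------------

def quasi_median(u, v, w):
    options = []
    for x, y, z in zip(u, v, w):
        c = Counter((x, y, z))
        state, top = c.most_common(1)[0]
        options.append([state] if top >= 2 else sorted(c))
    return [tuple(p) for p in itertools.product(*options)]


def hamming(a, b) -> int:
    return sum(x != y for x, y in zip(a, b))


def quasi_median_closure(observed) -> set:
    """Closure over all triples, then keep only vectors on a Hamming
    geodesic between two observed haplotypes."""
    nodes = set(observed)
    while True:
        new = set()
        for trip in itertools.combinations(sorted(nodes), 3):
            for m in quasi_median(*trip):
                if m not in nodes:
                    new.add(m)
        if not new:
            break
        nodes |= new
    keep = set(observed)
    for v in nodes - keep:
        if any(
            hamming(a, v) + hamming(v, b) == hamming(a, b)
            for a, b in itertools.combinations(observed, 2)
        ):
            keep.add(v)
    return keep


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def make_hapset(vectors, species=None, members=None, kinds=None) -> HaplotypeSet:
    """HaplotypeSet from raw state vectors (testing convenience)."""
    vectors = [tuple(v) for v in vectors]
    length = len(vectors[0])
    species = species or [{"sp1"}] * len(vectors)
    members = members or [[f"s{i}"] for i in range(len(vectors))]
    haps = [
        Haplotype(f"H{i + 1}", vec, list(mem), frozenset(sp))
        for i, (vec, mem, sp) in enumerate(zip(vectors, members, species))
    ]
    return HaplotypeSet(
        genus="Testus",
        combination=("locus1",),
        haplotypes=haps,
        n_sequenced=sum(len(m) for m in members),
        character_kinds=tuple(kinds) if kinds else ("sub",) * length,
    )


def make_table(spec: dict[str, list[str]], genus: str = "Testus") -> SpecimenTable:
    """SpecimenTable from {species: [specimen ids]}."""
    return SpecimenTable(
        [
            SpecimenRecord(sid, genus, species)
            for species, sids in spec.items()
            for sid in sids
        ]
    )


def identified_specimens(hs: HaplotypeSet) -> set[str]:
    return {
        m for h in hs.haplotypes if len(h.species) == 1 for m in h.members
    }
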