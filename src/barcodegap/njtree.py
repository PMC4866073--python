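"""Neighbour-Joining trees, nonparametric bootstrap, and species monophyly.

NJ (Saitou & Nei) is run on K2P distance matrices; it is the standard
tree method for barcode evaluation because the goal is specimen
clustering, not evolutionary inference.  Negative branch-length
estimates are clamped to zero with the deficit transferred to the
sister branch, and ties in the Q-criterion are broken by joining the
closest tied pair first, then the lowest (i, j) index pair, so the
reconstruction is deterministic and identical sequences group together
rather than stacking serially onto a cluster node.

Monophyly of a species is a rooting-free property here: the species is
monophyletic iff some edge of the unrooted tree separates exactly its
specimens from everything else.  Intruder specimens are reported from
the smallest clade spanning the species after midpoint rooting, which
is used for reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .distances import DistanceMatrix, distance_matrix_from_encoded
from .io_formats import DataError, SpecimenTable

logger = logging.getLogger(__name__)

Bipartition = frozenset  # canonical side of a split (the side without the ref leaf)


@dataclass
class Phylogeny:
    """Unrooted tree with branch lengths in substitutions/site."""

    newick: str
    supports: dict[Bipartition, float] | None = None

    _tree: dendropy.Tree | None = field(default=None, repr=False)

    @property
    def tree(self) -> dendropy.Tree:
        if self._tree is None:
            self._tree = dendropy.Tree.get(
                data=self.newick, schema="newick", preserve_underscores=True
            )
        return self._tree

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.taxon.label for l in self.tree.leaf_node_iter())

    def bipartitions(self, include_trivial: bool = False) -> set[Bipartition]:
        return tree_bipartitions(self.tree, include_trivial=include_trivial)

    def with_supports_newick(self) -> str:
        """Newick with bootstrap percentages as internal-node labels."""
        if self.supports is None:
            return self.newick
        tree = dendropy.Tree.get(
            data=self.newick, schema="newick", preserve_underscores=True
        )
        all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        ref = min(all_leaves)
        for nd in tree.preorder_internal_node_iter(exclude_seed_node=True):
            clade = frozenset(l.taxon.label for l in nd.leaf_iter())
            key = _canonical(clade, all_leaves, ref)
            if key in self.supports:
                nd.label = f"{self.supports[key]:.0f}"
        return tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()


def _canonical(side: frozenset, all_leaves: frozenset, ref: str) -> Bipartition:
    return frozenset(all_leaves - side) if ref in side else frozenset(side)


def tree_bipartitions(
    tree: dendropy.Tree, include_trivial: bool = False
) -> set[Bipartition]:
    """Non-trivial splits of an unrooted tree as canonical leaf sets."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_leaves)
    out: set[Bipartition] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        clade = frozenset(l.taxon.label for l in nd.leaf_iter())
        lo = 1 if include_trivial else 2
        if lo <= len(clade) <= len(all_leaves) - lo:
            out.add(_canonical(clade, all_leaves, ref))
    return out


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj(dm: DistanceMatrix) -> Phylogeny:
    """Saitou-Nei neighbour joining on a fully defined distance matrix."""
    if dm.n < 3:
        raise DataError("NJ requires at least 3 taxa")
    if dm.has_undefined():
        raise DataError(
            "distance matrix has undefined entries; exclude or impute the "
            f"offending pairs first: {dm.undefined_pairs()[:5]}"
        )
    D = dm.d.copy()
    nodes = list(dm.labels)

    def argmin_pair(Q: np.ndarray, Dcur: np.ndarray) -> tuple[int, int]:
        # among Q-minimal pairs join the closest pair first (identical
        # specimens group together instead of stacking onto a cluster
        # node), then the lowest (i, j) index pair — fully deterministic
        n = Q.shape[0]
        upper = np.triu(np.ones_like(Q, dtype=bool), k=1)
        masked = np.where(upper, Q, np.inf)
        qmin = masked.min()
        ties = np.argwhere(masked == qmin)
        k = int(np.lexsort((ties[:, 1], ties[:, 0], Dcur[ties[:, 0], ties[:, 1]]))[0])
        return int(ties[k, 0]), int(ties[k, 1])

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        i, j = argmin_pair(Q, D)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = new
        del nodes[j]

    # final star over the last three nodes: b_i = (d_ij + d_ik - d_jk) / 2
    b = [
        max(0.0, 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])),
        max(0.0, 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])),
        max(0.0, 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])),
    ]
    newick = (
        f"({nodes[0]}:{_fmt(b[0])},{nodes[1]}:{_fmt(b[1])},{nodes[2]}:{_fmt(b[2])});"
    )
    return Phylogeny(newick=newick)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative estimate to 0, moving the deficit to the sister."""
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def bootstrap(
    labels: list[str],
    encoded: np.ndarray,
    n_replicates: int = 100,
    seed: int = 0,
) -> Phylogeny:
    """NJ tree with bootstrap supports from column resampling.

    ``encoded`` is the (n x L) nucleotide matrix (codes 0-3, missing 4)
    of the concatenated alignment; all columns, constant ones included,
    are resampled with replacement.  Coded indel characters are not
    resampled because the tree itself is built from K2P, which ignores
    them.  A replicate whose matrix contains undefined distances is
    redrawn up to 10 times, then counted as non-supporting.
    """
    rng = np.random.default_rng(seed)
    dm = distance_matrix_from_encoded(labels, encoded)
    if dm.has_undefined():
        raise DataError("undefined distances in the full matrix; resolve first")
    base = nj(dm)
    target = base.bipartitions()

    n_variable = int(
        sum(len(set(col[col < 4])) >= 2 for col in encoded.T)
    )
    if n_variable == 0:
        logger.warning("invariant alignment: bootstrap supports undefined, set to 0")
        base.supports = {bip: 0.0 for bip in target}
        return base

    L = encoded.shape[1]
    tally = {bip: 0 for bip in target}
    for _ in range(n_replicates):
        rep_bips = None
        for _attempt in range(10):
            cols = rng.integers(0, L, size=L)
            rep_dm = distance_matrix_from_encoded(labels, encoded[:, cols])
            if rep_dm.has_undefined():
                continue
            rep_bips = nj(rep_dm).bipartitions()
            break
        if rep_bips is None:
            logger.warning("bootstrap replicate undefined after 10 redraws; "
                           "counted as non-supporting")
            continue
        for bip in target:
            if bip in rep_bips:
                tally[bip] += 1
    base.supports = {
        bip: 100.0 * count / n_replicates for bip, count in tally.items()
    }
    return base


@dataclass
class SpeciesMonophyly:
    species: str
    n_specimens: int
    monophyletic: bool
    trivial: bool           # single-specimen species
    intruders: list[str]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_specimens": self.n_specimens,
            "monophyletic": self.monophyletic,
            "trivial": self.trivial,
            "intruders": self.intruders,
        }


def _split_compatible(s: frozenset, a: frozenset, universe: frozenset) -> bool:
    b = universe - a
    return s <= a or s <= b or a <= s or b <= s


def monophyly(
    phylo: Phylogeny, specimens: SpecimenTable, tol: float = 1e-5
) -> list[SpeciesMonophyly]:
    """Split-compatibility monophyly test for every species on the tree.

    Near-zero internal branches are soft polytomies (NJ resolves ties
    between identical sequences arbitrarily, and round-off leaves
    lengths of order 1e-8 on them, while K2P non-additivity between
    near-identical sequences creates spurious branches of order p^2,
    ~1e-6 for within-species divergence), so a species counts as
    monophyletic iff its specimens-versus-rest split is compatible with
    every branch longer than ``tol``, i.e. the splits the distance data
    actually support.  ``tol`` of 1e-5 substitutions/site sits above
    those artifacts yet well below a single mutation on any realistic
    alignment (>= 1e-4 for a 10 kb barcode).  For
    a fully resolved tree with positive branch lengths this reduces to
    the classic test that some edge separates exactly the species'
    specimens.
    """
    leaves = phylo.leaf_labels()
    by_species: dict[str, set[str]] = {}
    for sid in leaves:
        by_species.setdefault(specimens.species_of(sid), set()).add(sid)
    if len(by_species) < 2:
        raise DataError("monophyly test requires at least 2 species on the tree")

    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    supported: list[frozenset] = []
    for nd in phylo.tree.preorder_node_iter():
        if nd.parent_node is None or (nd.edge.length or 0.0) <= tol:
            continue
        clade = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 2 <= len(clade) <= len(all_leaves) - 2:
            supported.append(_canonical(clade, all_leaves, ref))

    rooted = dendropy.Tree.get(
        data=phylo.newick, schema="newick", preserve_underscores=True
    )
    try:
        rooted.reroot_at_midpoint(update_bipartitions=False)
    except Exception:  # zero-length trees etc.: keep the input rooting
        pass

    out = []
    for species in sorted(by_species):
        members = frozenset(by_species[species])
        if len(members) == 1:
            out.append(SpeciesMonophyly(species, 1, True, True, []))
            continue
        mono = all(
            _split_compatible(members, s, all_leaves) for s in supported
        )
        intruders: list[str] = []
        if not mono:
            mrca = rooted.mrca(taxon_labels=sorted(members))
            clade = {l.taxon.label for l in mrca.leaf_iter()}
            intruders = sorted(clade - members)
        out.append(
            SpeciesMonophyly(species, len(members), mono, False, intruders)
        )
    return out
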