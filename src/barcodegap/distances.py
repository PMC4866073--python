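"""Kimura 2-parameter distances and barcoding-gap diagnostics.

The K2P model separates transitions (purine<->purine, pyrimidine<->
pyrimidine) from transversions.  With P and Q the observed proportions
of transitional and transversional differences over the comparable
sites of a pair,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence has a gap or N are excluded pair by pair
(pairwise deletion).  A pair with no comparable sites, or one whose
observed proportions push a logarithm out of domain (saturation), has
no defined distance; such entries are flagged, never silently zeroed.

The barcoding gap is assessed per species by comparing the maximum
intraspecific distance against the nearest-neighbour distance — the
minimum over other species of the mean interspecific distance.  A gap
is present when the nearest neighbour is farther than the most
divergent conspecific pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import DataError, LocusAlignment, SpecimenTable, sort_loci
from .haplotyping import combination_name

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i  # A=0 C=1 G=2 T=3; purines even, pyrimidines odd


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class K2PResult:
    distance: float
    P: float
    Q: float
    n_sites: int
    defined: bool
    reason: str = ""


def _k2p_from_counts(n_sites: int, transitions: int, transversions: int) -> K2PResult:
    if n_sites == 0:
        return K2PResult(math.nan, math.nan, math.nan, 0, False, "no comparable sites")
    P = transitions / n_sites
    Q = transversions / n_sites
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return K2PResult(math.nan, P, Q, n_sites, False, "saturation")
    d = -0.5 * math.log(a) - 0.25 * math.log(b)
    return K2PResult(d, P, Q, n_sites, True)


def k2p(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two aligned sequences with pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise DataError("sequences must have equal aligned length")
    a, b = encode(seq_a), encode(seq_b)
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    ts = diff & ((a & 1) == (b & 1))
    return _k2p_from_counts(int(valid.sum()), int(ts.sum()), int((diff & ~ts).sum()))


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray                 # K2P distances, nan where undefined
    comparable_sites: np.ndarray  # sites used per pair
    defined: np.ndarray           # bool mask, True where d is defined

    def __post_init__(self) -> None:
        n = len(self.labels)
        assert self.d.shape == (n, n)

    @property
    def n(self) -> int:
        return len(self.labels)

    def has_undefined(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool((~self.defined & off).any())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if not self.defined[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in keep]
        return DistanceMatrix(
            labels=list(keep),
            d=self.d[np.ix_(idx, idx)].copy(),
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)].copy(),
            defined=self.defined[np.ix_(idx, idx)].copy(),
        )


def distance_matrix_from_encoded(labels: Sequence[str], mat: np.ndarray) -> DistanceMatrix:
    """Pairwise K2P over an (n x L) encoded matrix (codes 0-3, missing=4)."""
    n = mat.shape[0]
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    defined = np.ones((n, n), dtype=bool)
    base = mat < 4
    parity = mat & 1
    for i in range(n):
        ai, vi, pi = mat[i], base[i], parity[i]
        for j in range(i + 1, n):
            valid = vi & base[j]
            diff = valid & (ai != mat[j])
            ts = int((diff & (pi == parity[j])).sum())
            tv = int(diff.sum()) - ts
            res = _k2p_from_counts(int(valid.sum()), ts, tv)
            d[i, j] = d[j, i] = res.distance
            sites[i, j] = sites[j, i] = res.n_sites
            defined[i, j] = defined[j, i] = res.defined
    sites[np.diag_indices(n)] = base.sum(axis=1)
    return DistanceMatrix(list(labels), d, sites, defined)


def distance_matrix(
    aln: LocusAlignment | Mapping[str, LocusAlignment],
    combination: Iterable[str] | None = None,
) -> DistanceMatrix:
    """All-pairs K2P for one alignment or a multi-locus concatenation.

    For combinations, only specimens sequenced at every locus enter the
    matrix; their sequences are concatenated before distance computation.
    """
    if isinstance(aln, Mapping):
        aln = concatenate(aln, combination if combination is not None else list(aln))
    labels = sorted(aln.rows)
    if len(labels) < 2:
        raise DataError("distance matrix requires at least 2 sequences")
    mat = np.stack([encode(aln.rows[sid]) for sid in labels])
    return distance_matrix_from_encoded(labels, mat)


def concatenate(
    alignments: Mapping[str, LocusAlignment], combination: Iterable[str]
) -> LocusAlignment:
    """Concatenate loci over the specimens sequenced at all of them."""
    loci = sort_loci(combination)
    if not loci:
        raise DataError("empty locus combination")
    missing = [l for l in loci if l not in alignments]
    if missing:
        raise DataError(f"no alignment for loci: {missing}")
    present = set(alignments[loci[0]].rows)
    for locus in loci[1:]:
        present &= set(alignments[locus].rows)
    if not present:
        raise DataError(f"no specimen sequenced at all of {loci}")
    rows = {
        sid: "".join(alignments[locus].rows[sid] for locus in loci)
        for sid in sorted(present)
    }
    genus = alignments[loci[0]].genus
    return LocusAlignment(genus=genus, locus=combination_name(loci), rows=rows)


@dataclass
class SpeciesGap:
    species: str
    n_specimens: int
    max_intraspecific: float | None
    nn_distance: float | None
    nearest_neighbor: str | None
    gap_present: bool | None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_specimens": self.n_specimens,
            "max_intraspecific": self.max_intraspecific,
            "nn_distance": self.nn_distance,
            "nearest_neighbor": self.nearest_neighbor,
            "gap_present": self.gap_present,
        }


@dataclass
class GapSummary:
    per_species: list[SpeciesGap]
    intraspecific: list[float]
    interspecific: list[float]
    n_dropped_pairs: int
    bin_width: float = 0.001

    def to_dict(self) -> dict:
        return {
            "per_species": [s.to_dict() for s in self.per_species],
            "intraspecific": self.intraspecific,
            "interspecific": self.interspecific,
            "n_dropped_pairs": self.n_dropped_pairs,
            "bin_width": self.bin_width,
        }

    def histograms(self) -> dict:
        """Fixed-width histograms of the pooled distance distributions."""
        pooled = self.intraspecific + self.interspecific
        top = max(pooled, default=0.0)
        edges = np.arange(0.0, top + 2 * self.bin_width, self.bin_width)
        intra, _ = np.histogram(self.intraspecific, bins=edges)
        inter, _ = np.histogram(self.interspecific, bins=edges)
        return {
            "bin_edges": edges.tolist(),
            "intraspecific": intra.tolist(),
            "interspecific": inter.tolist(),
        }


def barcoding_gap(
    dm: DistanceMatrix, specimens: SpecimenTable, bin_width: float = 0.001
) -> GapSummary:
    """Per-species gap diagnostics plus pooled intra/inter distance lists."""
    species_of = {l: specimens.species_of(l) for l in dm.labels}
    species = sorted(set(species_of.values()))
    if len(species) < 2:
        raise DataError("barcoding gap requires at least 2 species")

    intra: list[float] = []
    inter: list[float] = []
    dropped = 0
    # cross[a][b]: defined distances between species a and b (a != b)
    cross: dict[str, dict[str, list[float]]] = {
        a: {b: [] for b in species if b != a} for a in species
    }
    within: dict[str, list[float]] = {a: [] for a in species}

    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            sa, sb = species_of[dm.labels[i]], species_of[dm.labels[j]]
            if not dm.defined[i, j]:
                dropped += 1
                continue
            dij = float(dm.d[i, j])
            if sa == sb:
                intra.append(dij)
                within[sa].append(dij)
            else:
                inter.append(dij)
                cross[sa][sb].append(dij)
                cross[sb][sa].append(dij)
    if dropped:
        logger.warning("dropped %d undefined pairwise distances", dropped)

    per_species = []
    counts = {sp: sum(1 for s in species_of.values() if s == sp) for sp in species}
    for sp in species:
        max_intra = max(within[sp]) if within[sp] else None
        means = {
            other: float(np.mean(vals))
            for other, vals in cross[sp].items()
            if vals
        }
        if means:
            nearest = min(means, key=lambda o: (means[o], o))
            nn = means[nearest]
        else:
            nearest, nn = None, None
        gap = (nn > max_intra) if (nn is not None and max_intra is not None) else None
        per_species.append(
            SpeciesGap(sp, counts[sp], max_intra, nn, nearest, gap)
        )
    return GapSummary(per_species, intra, inter, dropped, bin_width)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix; undefined entries written as -1."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, label in enumerate(dm.labels):
            vals = [
                f"{dm.d[i, j]:.6f}" if dm.defined[i, j] or i == j else "-1.000000"
                for j in range(dm.n)
            ]
            fh.write(f"{label:<10s} " + " ".join(vals) + "\n")


def plot_gap_histogram(summary: GapSummary, path: str | Path) -> None:
    """Overlaid histograms of intra- vs interspecific K2P distances."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = summary.histograms()
    edges = np.asarray(hist["bin_edges"])
    fig, ax = plt.subplots(figsize=(6, 4))
    width = summary.bin_width
    ax.bar(edges[:-1], hist["intraspecific"], width=width, align="edge",
           color="0.8", label="intraspecific")
    ax.bar(edges[:-1], hist["interspecific"], width=width, align="edge",
           color="0.3", alpha=0.7, label="interspecific")
    ax.set_xlabel("K2P distance (substitutions/site)")
    ax.set_ylabel("pairs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
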