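"""Rarefaction sequence richness and sampling-size correlations.

Sequence richness Rs(g) is the expected number of distinct haplotypes
recovered in a random subsample of g individuals drawn without
replacement, computed from the observed haplotype frequencies N_k
(Hurlbert-style rarefaction):

    Rs(g) = sum_k [ 1 - C(N - N_k, g) / C(N, g) ]

with C(a, b) = 0 when a < b.  It quantifies how much of a species'
sequence diversity a small sample (default g = 3) would capture.

Correlations between sampling size and the number of unique sequences
use the sample Pearson coefficient with Fisher r-to-z confidence
intervals: z = atanh(r), SE = 1/sqrt(n - 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import special, stats

from .io_formats import DataError

#: switch from exact integer binomials to log-gamma above this N
_EXACT_N_LIMIT = 1000


@dataclass
class RarefactionResult:
    species: str
    N: int
    frequencies: list[int]
    g: int
    Rs: float

    def to_dict(self) -> dict:
        return asdict(self)


def _comb_ratio(a: int, n: int, g: int) -> float:
    """C(a, g) / C(n, g) with C(x, g) = 0 for x < g."""
    if a < g:
        return 0.0
    if n <= _EXACT_N_LIMIT:
        return math.comb(a, g) / math.comb(n, g)
    log_ratio = (
        special.gammaln(a + 1)
        - special.gammaln(a - g + 1)
        - special.gammaln(n + 1)
        + special.gammaln(n - g + 1)
    )
    return float(np.exp(log_ratio))


def rarefied_richness(frequencies: Sequence[int], g: int) -> float:
    """Expected distinct haplotypes in a subsample of g individuals."""
    if not frequencies:
        raise DataError("empty frequency vector")
    if any(f < 1 for f in frequencies):
        raise DataError("all haplotype counts must be >= 1")
    n = sum(frequencies)
    if g < 1 or g > n:
        raise DataError(f"subsample size g={g} outside 1..{n}")
    return float(sum(1.0 - _comb_ratio(n - nk, n, g) for nk in frequencies))


def rarefaction_result(
    species: str, frequencies: Sequence[int], g: int = 3
) -> RarefactionResult:
    return RarefactionResult(
        species=species,
        N=sum(frequencies),
        frequencies=sorted(frequencies, reverse=True),
        g=g,
        Rs=rarefied_richness(frequencies, g),
    )


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p_two_tailed: float
    p_one_tailed: float
    defined: bool = True
    reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def pearson_fisher(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with Fisher r-to-z interval and normal p-value.

    Perfect correlations (|r| = 1) have a degenerate interval [r, r] and
    a p-value reported as 0.0 (below the machine floor).  Zero variance
    in either variable leaves r undefined (flagged, not an exception).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise DataError("Fisher r-to-z requires n >= 4 (SE = 1/sqrt(n-3))")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            math.nan, n, math.nan, math.nan, math.nan, math.nan,
            defined=False, reason="zero variance",
        )
    r = float(stats.pearsonr(x, y).statistic)
    se = 1.0 / math.sqrt(n - 3)
    if abs(r) >= 1.0:
        r = math.copysign(1.0, r)
        return CorrelationResult(r, n, r, r, 0.0, 0.0)
    z = math.atanh(r)
    ci_low = math.tanh(z - 1.959963984540054 * se)
    ci_high = math.tanh(z + 1.959963984540054 * se)
    p_two = 2.0 * float(stats.norm.sf(abs(z) / se))
    return CorrelationResult(r, n, ci_low, ci_high, min(p_two, 1.0), min(p_two, 1.0) / 2.0)
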