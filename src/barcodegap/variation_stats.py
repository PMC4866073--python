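"""Per-alignment diversity measures.

For each genus x locus alignment we report the aligned length, the
sequencing success (share of the genus' specimens with a sequence at the
locus), the percentage of conserved sites and the percentage of
parsimony-informative sites.  Gaps and N are treated as missing data for
site classification — indel variation is scored separately during
haplotype coding, not here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

from .io_formats import DataError, LocusAlignment, SpecimenTable, VALID_CHARS

#: site categories
CONSERVED = "conserved"
VARIABLE_UNINFORMATIVE = "variable_uninformative"
PARSIMONY_INFORMATIVE = "parsimony_informative"
EXCLUDED = "excluded"


@dataclass
class VariationSummary:
    genus: str
    locus: str
    aligned_length: int
    sequencing_success: float
    conserved_sites: float
    parsimony_informative_sites: float

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 1) -> dict:
        d = self.to_dict()
        for k in ("sequencing_success", "conserved_sites", "parsimony_informative_sites"):
            d[k] = round(d[k], ndigits)
        return d


def classify_column(column) -> str:
    """Classify one alignment column.

    Ignoring N and ``-``: *conserved* if at most one distinct base is
    present, *parsimony informative* if at least two bases each occur in
    at least two sequences, *variable uninformative* otherwise.  Columns
    with fewer than two comparable characters are *excluded*.
    """
    if len(column) == 0:
        raise DataError("empty column")
    bad = set(column) - VALID_CHARS
    if bad:
        raise DataError(f"invalid characters in column: {sorted(bad)}")
    counts = Counter(c for c in column if c not in "N-")
    if sum(counts.values()) < 2:
        return EXCLUDED
    if len(counts) <= 1:
        return CONSERVED
    if sum(1 for n in counts.values() if n >= 2) >= 2:
        return PARSIMONY_INFORMATIVE
    return VARIABLE_UNINFORMATIVE


def summarize_variation(
    aln: LocusAlignment,
    specimens: SpecimenTable,
    site_denominator: str = "all",
) -> VariationSummary:
    """Site-category percentages and sequencing success for one alignment.

    ``site_denominator`` selects the dialect for the percentage base:
    ``all`` (default) divides by the full aligned length, matching how
    such tables are conventionally reported against "aligned length
    (bp)"; ``ungapped`` divides by the number of non-excluded columns.
    """
    if len(aln.rows) < 2:
        raise DataError("variation undefined for alignments with fewer than 2 rows")
    if site_denominator not in ("all", "ungapped"):
        raise ValueError(f"unknown site denominator: {site_denominator!r}")

    tallies = Counter(classify_column(aln.column(i)) for i in range(aln.length))
    denom = aln.length if site_denominator == "all" else aln.length - tallies[EXCLUDED]
    if denom == 0:
        raise DataError("no countable columns in alignment")

    genus_n = len(specimens.specimens_of_genus(aln.genus))
    if genus_n == 0:
        raise DataError(f"no specimens of genus {aln.genus!r} in table")

    return VariationSummary(
        genus=aln.genus,
        locus=aln.locus,
        aligned_length=aln.length,
        sequencing_success=100.0 * len(aln.rows) / genus_n,
        conserved_sites=100.0 * tallies[CONSERVED] / denom,
        parsimony_informative_sites=100.0 * tallies[PARSIMONY_INFORMATIVE] / denom,
    )
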