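"""Haplotype coding, collapsing, and assignment success per locus combination.

A specimen's sequence at a locus is re-expressed as a vector of coded
characters:

* substitution characters — one per variable nucleotide column;
* indel characters — one binary presence/absence character per maximal
  gap run with identical boundaries (simple indel coding), so an
  insertion/deletion of any length counts as a single mutation step;
* structural characters — one multistate character per user-annotated
  event (e.g. an inversion), whose state is the sequence content of the
  annotated window; any two distinct states are one step apart.  The
  window's nucleotide columns are masked from substitution characters.

Specimens with identical coded vectors across all loci of a combination
form one haplotype.  A haplotype observed in exactly one species is
*private*; specimens carrying a private haplotype are unambiguously
identified, and the share of such specimens is the assignment success
of the combination.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import CANONICAL_LOCI, DataError, LocusAlignment, SpecimenTable, sort_loci

#: state token for inapplicable / unknown coded characters
MISSING = "?"

#: multi-locus combination names used when the four canonical plastid
#: loci are analysed (single loci are reported under their own name)
OPTION_NAMES = {
    ("matK", "rpoC1"): "Option1",
    ("matK", "rpoB"): "Option2",
    ("matK", "trnH-psbA"): "Option3",
    ("rpoB", "rpoC1"): "Option4",
    ("rpoC1", "trnH-psbA"): "Option5",
    ("rpoB", "trnH-psbA"): "Option6",
    ("matK", "rpoB", "rpoC1"): "Option7",
    ("matK", "rpoC1", "trnH-psbA"): "Option8",
    ("matK", "rpoB", "trnH-psbA"): "Option9",
    ("rpoB", "rpoC1", "trnH-psbA"): "Option10",
    ("matK", "rpoB", "rpoC1", "trnH-psbA"): "Option11",
}


@dataclass(frozen=True)
class StructuralEvent:
    """User-annotated structural mutation (inversion, multi-bp event).

    ``start``/``end`` are 0-based inclusive alignment columns.
    """

    event_type: str
    start: int
    end: int


@dataclass(frozen=True)
class CodedCharacter:
    kind: str          # 'sub' | 'indel' | 'struct'
    start: int         # alignment column (sub: the column; indel/struct: run start)
    end: int           # inclusive end column

    def describe(self) -> str:
        if self.kind == "sub":
            return f"sub@{self.start + 1}"
        return f"{self.kind}@{self.start + 1}-{self.end + 1}"


@dataclass
class CodedMatrix:
    """Coded character-state matrix for one genus x locus."""

    genus: str
    locus: str
    characters: list[CodedCharacter]
    states: dict[str, tuple[str, ...]]  # specimen_id -> state vector

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.states)

    def vector(self, specimen_id: str) -> tuple[str, ...]:
        return self.states[specimen_id]


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as (start, end) inclusive."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(seq) - 1))
    return runs


def code_alignment(
    aln: LocusAlignment,
    annotations: Sequence[StructuralEvent] | None = None,
) -> CodedMatrix:
    """Recode an alignment as substitution + indel + structural characters.

    Simple indel coding: each maximal gap run with identical boundaries
    shared by the specimens that carry it becomes one binary character.
    A specimen whose own gap run strictly contains the character's run
    cannot be scored for it and gets a missing state.  Runs present in
    every row are invariant and yield no character.
    """
    annotations = list(annotations or [])
    for ev in annotations:
        if not (0 <= ev.start <= ev.end < aln.length):
            raise DataError(
                f"structural annotation {ev.event_type} {ev.start}-{ev.end} "
                f"outside alignment bounds (length {aln.length})"
            )
    masked_cols = set()
    for ev in annotations:
        masked_cols.update(range(ev.start, ev.end + 1))

    sids = list(aln.rows)
    runs_by_sid = {sid: _gap_runs(aln.rows[sid]) for sid in sids}

    # candidate indel characters: distinct runs, minus invariant ones and
    # those fully inside an annotated structural window
    all_runs = sorted({run for runs in runs_by_sid.values() for run in runs})
    indel_chars = []
    for run in all_runs:
        if all(run in runs_by_sid[sid] for sid in sids):
            continue  # invariant gap, no variation to code
        if any(ev.start <= run[0] and run[1] <= ev.end for ev in annotations):
            continue  # covered by a structural character
        indel_chars.append(run)

    def indel_state(sid: str, run: tuple[int, int]) -> str:
        own = runs_by_sid[sid]
        if run in own:
            return "1"
        for s2, e2 in own:
            if s2 <= run[0] and run[1] <= e2:
                return MISSING  # nested inside a longer gap: unscorable
        return "0"

    # substitution characters: columns with >=2 distinct non-gap symbols
    # (N counts as a distinct symbol so that strict haplotype identity can
    # see it; purely gap-driven variation is carried by indel characters)
    sub_cols = []
    for col in range(aln.length):
        if col in masked_cols:
            continue
        symbols = {aln.rows[sid][col] for sid in sids} - {"-"}
        if len(symbols) >= 2:
            sub_cols.append(col)

    characters: list[CodedCharacter] = []
    vectors: dict[str, list[str]] = {sid: [] for sid in sids}
    for col in sub_cols:
        characters.append(CodedCharacter("sub", col, col))
        for sid in sids:
            vectors[sid].append(aln.rows[sid][col])
    for run in indel_chars:
        characters.append(CodedCharacter("indel", run[0], run[1]))
        for sid in sids:
            vectors[sid].append(indel_state(sid, run))
    for ev in annotations:
        window_states = {sid: aln.rows[sid][ev.start : ev.end + 1] for sid in sids}
        if len(set(window_states.values())) < 2:
            continue  # invariant window
        characters.append(CodedCharacter("struct", ev.start, ev.end))
        for sid in sids:
            vectors[sid].append(window_states[sid])

    return CodedMatrix(
        genus=aln.genus,
        locus=aln.locus,
        characters=characters,
        states={sid: tuple(vec) for sid, vec in vectors.items()},
    )


@dataclass
class Haplotype:
    label: str
    vector: tuple[str, ...]
    members: list[str]
    species: frozenset[str]


@dataclass
class HaplotypeSet:
    genus: str
    combination: tuple[str, ...]
    haplotypes: list[Haplotype]
    n_sequenced: int
    character_kinds: tuple[str, ...] = ()

    def member_counts(self) -> dict[str, int]:
        return {h.label: len(h.members) for h in self.haplotypes}


def _is_compatible(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    wild = (MISSING, "N")
    return all(x == y or x in wild or y in wild for x, y in zip(a, b))


def collapse_haplotypes(
    coded: Mapping[str, CodedMatrix] | Sequence[CodedMatrix],
    combination: Iterable[str],
    specimens: SpecimenTable,
    ambiguity: str = "strict",
) -> HaplotypeSet:
    """Collapse coded vectors into unique haplotypes for a locus combination.

    Only specimens with data at every locus of the combination enter the
    set (their vectors are concatenated in canonical locus order).
    Under the default ``strict`` rule two specimens share a haplotype
    only if their vectors are exactly identical (N is a distinct token);
    ``compatible`` additionally merges vectors that differ only where one
    has missing data, greedily in sorted specimen order.
    """
    if not isinstance(coded, Mapping):
        coded = {cm.locus: cm for cm in coded}
    combination = sort_loci(combination)
    if not combination:
        raise DataError("empty locus combination")
    missing_loci = [l for l in combination if l not in coded]
    if missing_loci:
        raise DataError(f"no coded matrix for loci: {missing_loci}")
    genera = {coded[l].genus for l in combination}
    if len(genera) > 1:
        raise DataError(f"coded matrices from different genera: {sorted(genera)}")
    if ambiguity not in ("strict", "compatible"):
        raise ValueError(f"unknown ambiguity rule: {ambiguity!r}")

    present = set(coded[combination[0]].states)
    for locus in combination[1:]:
        present &= set(coded[locus].states)
    present = sorted(present)

    kinds = tuple(
        ch.kind for locus in combination for ch in coded[locus].characters
    )

    def concat(sid: str) -> tuple[str, ...]:
        vec: list[str] = []
        for locus in combination:
            vec.extend(coded[locus].vector(sid))
        return tuple(vec)

    classes: list[tuple[tuple[str, ...], list[str]]] = []
    index: dict[tuple[str, ...], int] = {}
    for sid in present:
        vec = concat(sid)
        if ambiguity == "strict":
            i = index.get(vec)
            if i is None:
                index[vec] = len(classes)
                classes.append((vec, [sid]))
            else:
                classes[i][1].append(sid)
        else:
            for vec0, members in classes:
                if _is_compatible(vec, vec0):
                    members.append(sid)
                    break
            else:
                classes.append((vec, [sid]))

    haplotypes = [
        Haplotype(
            label=f"H{i + 1}",
            vector=vec,
            members=members,
            species=frozenset(specimens.species_of(s) for s in members),
        )
        for i, (vec, members) in enumerate(classes)
    ]
    return HaplotypeSet(
        genus=genera.pop() if genera else "",
        combination=tuple(combination),
        haplotypes=haplotypes,
        n_sequenced=len(present),
        character_kinds=kinds,
    )


def combination_name(loci: Iterable[str]) -> str:
    loci = tuple(sorted(loci))
    if len(loci) == 1:
        return loci[0]
    return OPTION_NAMES.get(loci, "+".join(sort_loci(loci)))


def assignment_success(hs: HaplotypeSet) -> dict:
    """One combination-report row: private haplotypes and identified specimens."""
    private = [h for h in hs.haplotypes if len(h.species) == 1]
    n_identified = sum(len(h.members) for h in private)
    percent = (
        100.0 * n_identified / hs.n_sequenced if hs.n_sequenced else math.nan
    )
    return {
        "combination": combination_name(hs.combination),
        "loci": list(hs.combination),
        "n_sequenced": hs.n_sequenced,
        "n_haplotypes": len(hs.haplotypes),
        "n_private_haplotypes": len(private),
        "n_individuals_identified": n_identified,
        "percent_identified": percent,
    }


def all_combinations(loci: Iterable[str]) -> list[tuple[str, ...]]:
    """All non-empty locus subsets, smallest first, canonical order within size."""
    loci = sort_loci(loci)
    out = []
    for k in range(1, len(loci) + 1):
        out.extend(itertools.combinations(loci, k))
    return out


def evaluate_combinations(
    coded: Mapping[str, CodedMatrix],
    specimens: SpecimenTable,
    ambiguity: str = "strict",
) -> list[dict]:
    """Assignment-success rows for every non-empty locus combination."""
    rows = []
    for combo in all_combinations(coded):
        hs = collapse_haplotypes(coded, combo, specimens, ambiguity=ambiguity)
        rows.append(assignment_success(hs))
    return rows


def best_barcode(reports: Sequence[dict]) -> tuple[list[dict], dict]:
    """Rank combinations by assignment success.

    Ties are broken in favour of fewer loci (parsimony of effort), then
    larger n_sequenced, then name — so the ranking is deterministic.
    """
    if not reports:
        raise DataError("no combinations evaluated")

    def key(row: dict):
        pct = row["percent_identified"]
        pct = -math.inf if pct is None or math.isnan(pct) else pct
        return (-pct, len(row["loci"]), -row["n_sequenced"], row["combination"])

    ranking = sorted(reports, key=key)
    return ranking, ranking[0]
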