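"""Reading and writing of on-disk artifacts.

The pipeline works from two kinds of input files:

* one aligned FASTA per genus x locus (gap character ``-``), where the
  first whitespace-delimited token of each header is the specimen id;
* a specimen metadata table (TSV) with columns
  ``specimen_id, genus, species, latitude, longitude`` (the last two
  optional).

Outputs are newick trees, TSV/JSON summary tables, TSV edge lists and
GraphML for haplotype networks.  All readers normalise sequences to the
alphabet ``{A, C, G, T, N, -}``: lowercase is upper-cased, ``U`` becomes
``T`` and IUPAC ambiguity codes other than ``N`` are mapped to ``N`` with
a logged warning (they would be ignored by pairwise-deletion distance
computations anyway).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: canonical plastid barcode loci, in reporting order
CANONICAL_LOCI = ("matK", "rpoC1", "rpoB", "trnH-psbA")

VALID_CHARS = frozenset("ACGTN-")
#: IUPAC ambiguity codes collapsed to N on input
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    genus: str
    species: str
    latitude: float | None = None
    longitude: float | None = None


@dataclass
class SpecimenTable:
    """Specimen -> (genus, species) mapping; the unit of assignment.

    Invariants: specimen ids are unique and every species belongs to
    exactly one genus.
    """

    records: list[SpecimenRecord]

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate specimen ids: {dupes}")
        species_genus: dict[str, str] = {}
        for r in self.records:
            prev = species_genus.setdefault(r.species, r.genus)
            if prev != r.genus:
                raise DataError(
                    f"species {r.species!r} mapped to two genera: {prev!r}, {r.genus!r}"
                )
        self._by_id = {r.specimen_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self._by_id

    def __getitem__(self, specimen_id: str) -> SpecimenRecord:
        return self._by_id[specimen_id]

    def species_of(self, specimen_id: str) -> str:
        return self._by_id[specimen_id].species

    def genera(self) -> list[str]:
        return sorted({r.genus for r in self.records})

    def specimens_of_genus(self, genus: str) -> list[str]:
        return [r.specimen_id for r in self.records if r.genus == genus]

    def species_of_genus(self, genus: str) -> list[str]:
        return sorted({r.species for r in self.records if r.genus == genus})

    def specimens_of_species(self, species: str) -> list[str]:
        return [r.specimen_id for r in self.records if r.species == species]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpecimenTable":
        df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
        required = {"specimen_id", "genus", "species"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"metadata table missing columns: {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            lat = getattr(row, "latitude", None)
            lon = getattr(row, "longitude", None)
            lat = None if lat is None or (isinstance(lat, float) and math.isnan(lat)) else float(lat)
            lon = None if lon is None or (isinstance(lon, float) and math.isnan(lon)) else float(lon)
            records.append(
                SpecimenRecord(str(row.specimen_id), str(row.genus), str(row.species), lat, lon)
            )
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "specimen_id": r.specimen_id,
                "genus": r.genus,
                "species": r.species,
                "latitude": "" if r.latitude is None else r.latitude,
                "longitude": "" if r.longitude is None else r.longitude,
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class LocusAlignment:
    """One gapped alignment for a genus x locus.

    Specimens without a sequence at this locus are simply absent from
    ``rows`` — absence (sequencing dropout) and gap (indel) mean
    different things downstream.
    """

    genus: str
    locus: str
    rows: dict[str, str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise DataError(f"empty alignment for {self.genus}/{self.locus}")
        lengths = {sid: len(seq) for sid, seq in self.rows.items()}
        uniq = set(lengths.values())
        if len(uniq) > 1:
            bad = min(lengths, key=lambda s: (lengths[s], s))
            raise DataError(
                f"ragged alignment in {self.genus}/{self.locus}: record {bad!r} "
                f"has length {lengths[bad]}, others {sorted(uniq - {lengths[bad]})}"
            )
        self.length = uniq.pop()
        for sid, seq in self.rows.items():
            bad_chars = set(seq) - VALID_CHARS
            if bad_chars:
                raise DataError(
                    f"invalid characters {sorted(bad_chars)} in record {sid!r}"
                )
            if set(seq) == {"-"}:
                raise DataError(f"record {sid!r} is all-gap; drop the row instead")

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> list[str]:
        return [seq[i] for seq in self.rows.values()]


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Upper-case, map U->T, collapse IUPAC ambiguity codes to N."""
    seq = raw.upper().replace("U", "T")
    amb = set(seq) & AMBIGUITY_CODES
    if amb:
        logger.warning(
            "record %s: ambiguity codes %s mapped to N", record_id, sorted(amb)
        )
        seq = "".join("N" if c in AMBIGUITY_CODES else c for c in seq)
    return seq


def read_alignment(
    path: str | Path, genus: str, locus: str, specimens: SpecimenTable
) -> LocusAlignment:
    """Read one aligned FASTA into a validated :class:`LocusAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"empty or non-FASTA file: {path}")
    rows: dict[str, str] = {}
    for rec in records:
        sid = rec.id.split()[0]
        if sid not in specimens:
            raise DataError(f"{path}: header {sid!r} not in specimen table")
        if specimens[sid].genus != genus:
            raise DataError(
                f"{path}: specimen {sid!r} belongs to genus "
                f"{specimens[sid].genus!r}, not {genus!r}"
            )
        if sid in rows:
            raise DataError(f"{path}: duplicate record {sid!r}")
        rows[sid] = normalize_sequence(str(rec.seq), sid)
    return LocusAlignment(genus=genus, locus=locus, rows=rows)


def write_alignment(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# generic report serialisation
# ---------------------------------------------------------------------------

def write_report(results, path: str | Path, format: str = "json") -> None:
    """Serialise a report object (dict, or list of flat dicts) to disk.

    JSON writes are canonical (sorted keys, no timestamps) so identical
    inputs produce byte-identical files.  TSV expects a list of flat
    dicts (rows) and writes a header even when empty.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(results, dict):
            results = [results]
        columns = list(results[0]) if results else []
        pd.DataFrame(results, columns=columns or None).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path, format: str = "json"):
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            return []
        return df.to_dict(orient="records")
    raise ValueError(f"unknown report format: {format!r}")


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)!r}")


def discover_alignments(
    directory: str | Path, specimens: SpecimenTable
) -> dict[str, dict[str, LocusAlignment]]:
    """Scan a directory of ``{genus}_{locus}.fasta`` files.

    Returns ``{genus: {locus: LocusAlignment}}``.  The locus part may
    itself contain underscores only if it matches a canonical locus
    name; otherwise the split is on the first underscore.
    """
    directory = Path(directory)
    out: dict[str, dict[str, LocusAlignment]] = {}
    for path in sorted(directory.glob("*.fasta")):
        stem = path.stem
        genus, _, locus = stem.partition("_")
        if not locus:
            raise DataError(f"cannot parse genus/locus from file name: {path.name}")
        aln = read_alignment(path, genus, locus, specimens)
        out.setdefault(genus, {})[locus] = aln
    return out


def sort_loci(loci: Iterable[str]) -> list[str]:
    """Canonical plastid loci first (matK, rpoC1, rpoB, trnH-psbA), rest sorted."""
    loci = list(loci)
    key = {name: i for i, name in enumerate(CANONICAL_LOCI)}
    return sorted(loci, key=lambda l: (key.get(l, len(key)), l))
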