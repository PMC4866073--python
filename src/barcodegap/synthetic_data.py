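"""Synthetic per-genus multi-locus datasets with known ground truth.

The generator emulates the evolutionary scenarios that govern plastid
barcode performance in closely related plants:

* species pairs sharing identical haplotypes through incomplete lineage
  sorting (retained ancestral polymorphism);
* chloroplast capture — a species harbouring two haplotype classes tens
  of mutations apart, one class shared with a non-sister donor species;
* monomorphic species;
* indel-rich non-coding loci (the trnH-psbA spacer) against conserved
  coding loci (matK, rpoC1, rpoB);
* per-locus sequencing dropout.

Haplotype lineages evolve along a user-supplied species tree with
Poisson substitution counts per branch (transition:transversion 2:1,
so the data sit inside the K2P model class) and Poisson indel events
with geometric lengths (mean 3 bp).  The default regime is
infinite-sites: every mutation hits a fresh alignment column and indel
regions are disjoint with a one-column buffer, so true pairwise step
counts are exact set differences of mutation events and match the coded
Hamming distances downstream with no homoplasy.

Haplotype sharing is injected by explicit events rather than by a full
coalescent: the claims under test concern the *patterns* (who shares
what, how far apart the classes are), not coalescent parameters.
Specimen counts per haplotype lineage are fixed integers, not
multinomial draws, so designed frequencies — and therefore designed
assignment success — are met exactly on every seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import (
    DataError,
    LocusAlignment,
    SpecimenRecord,
    SpecimenTable,
    write_alignment,
)

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class LocusSpec:
    name: str
    length: int
    substitution_rate: float  # expected substitutions per site per time unit
    indel_rate: float = 0.0   # expected indel events per site per time unit


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    n_specimens: int
    #: (lineage reference, specimen count); references are "modal",
    #: "v1", "v2", ... (per-species variants) or global event labels
    #: ("ils0", "cap0", ...).  None means everyone on the modal lineage.
    composition: tuple[tuple[str, int], ...] | None = None


@dataclass(frozen=True)
class IlsEvent:
    """Ancestral haplotype retained across >=2 species.

    The shared lineage is the most recent common ancestor of the listed
    species, plus ``offset_steps`` extra substitutions so that several
    distinct retained polymorphisms can coexist.
    """

    species: tuple[str, ...]
    offset_steps: int = 0


@dataclass(frozen=True)
class CaptureEvent:
    """Chloroplast capture: the recipient acquires a foreign haplotype.

    The captured lineage is built ``divergence_steps`` substitutions
    away from the recipient's own modal haplotype, concentrated on
    ``locus``; with ``shared`` it is also placed in the donor's pool
    (the biological signature: one deeply divergent intraspecific class,
    identical to a non-sister species' sequence).
    """

    donor: str
    recipient: str
    divergence_steps: int
    locus: str = "trnH-psbA"
    shared: bool = True


@dataclass
class ScenarioConfig:
    genus_name: str
    species: tuple[SpeciesSpec, ...]
    loci: tuple[LocusSpec, ...]
    tree: str  # newick over species names, branch lengths in time units
    ils_events: tuple[IlsEvent, ...] = ()
    capture_events: tuple[CaptureEvent, ...] = ()
    #: per-species extra haplotype lineages: species -> steps for v1, v2, ...
    variant_steps: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    #: locus -> dropout probability (optionally per species: locus -> {species: p})
    dropout: Mapping[str, object] = field(default_factory=dict)
    #: expected barcoding-gap outcome per species (only asserted species)
    designed_gap: Mapping[str, bool] = field(default_factory=dict)
    #: loci forming the scenario's reference barcode for designed statistics
    barcode_loci: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species or not self.loci:
            raise DataError("scenario needs at least one species and one locus")
        for sp in self.species:
            if sp.n_specimens < 1:
                raise DataError(f"{sp.name}: n_specimens must be >= 1")
            if sp.composition is not None:
                total = sum(c for _, c in sp.composition)
                if total != sp.n_specimens:
                    raise DataError(
                        f"{sp.name}: composition sums to {total}, "
                        f"n_specimens is {sp.n_specimens}"
                    )
        for lc in self.loci:
            if lc.substitution_rate < 0 or lc.indel_rate < 0 or lc.length < 1:
                raise DataError(f"{lc.name}: invalid length or rates")
        for ev in self.capture_events:
            if ev.divergence_steps < 1:
                raise DataError("capture divergence_steps must be >= 1")

    def locus_names(self) -> list[str]:
        return [lc.name for lc in self.loci]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

Subs = frozenset  # of (locus, column, to_base)
Indels = frozenset  # of (locus, start, length)


@dataclass
class GroundTruth:
    genus: str
    lineage_subs: dict[str, Subs]
    lineage_indels: dict[str, Indels]
    specimen_lineage: dict[str, str]
    specimen_species: dict[str, str]
    designed_gap: dict[str, bool]
    barcode_loci: tuple[str, ...]
    designed_private_percent: float
    seed: int

    def steps_between(
        self, lineage_a: str, lineage_b: str, loci: Sequence[str] | None = None
    ) -> int:
        """True mutation steps between two lineages over the given loci."""
        loci_set = None if loci is None else set(loci)

        def restrict(events, idx=0):
            if loci_set is None:
                return events
            return frozenset(e for e in events if e[idx] in loci_set)

        subs = restrict(self.lineage_subs[lineage_a]) ^ restrict(
            self.lineage_subs[lineage_b]
        )
        indels = restrict(self.lineage_indels[lineage_a]) ^ restrict(
            self.lineage_indels[lineage_b]
        )
        return len(subs) + len(indels)

    def private_percent(self, loci: Sequence[str]) -> float:
        """Share of specimens whose haplotype (over ``loci``) is species-private."""
        key_of = {}
        for sid, lin in self.specimen_lineage.items():
            loci_set = set(loci)
            key_of[sid] = (
                frozenset(e for e in self.lineage_subs[lin] if e[0] in loci_set),
                frozenset(e for e in self.lineage_indels[lin] if e[0] in loci_set),
            )
        species_of = self.specimen_species
        by_key: dict[tuple, set[str]] = {}
        for sid, key in key_of.items():
            by_key.setdefault(key, set()).add(species_of[sid])
        n_private = sum(
            1 for sid, key in key_of.items() if len(by_key[key]) == 1
        )
        return 100.0 * n_private / len(key_of)

    def to_dict(self) -> dict:
        return {
            "genus": self.genus,
            "seed": self.seed,
            "barcode_loci": list(self.barcode_loci),
            "designed_gap": dict(self.designed_gap),
            "designed_private_percent": self.designed_private_percent,
            "specimen_lineage": dict(sorted(self.specimen_lineage.items())),
            "specimen_species": dict(sorted(self.specimen_species.items())),
            "lineage_subs": {
                k: sorted(list(e) for e in v) for k, v in sorted(self.lineage_subs.items())
            },
            "lineage_indels": {
                k: sorted(list(e) for e in v)
                for k, v in sorted(self.lineage_indels.items())
            },
        }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


class _ColumnAllocator:
    """Hands out fresh alignment columns (infinite-sites bookkeeping)."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.length = length
        self.rng = rng
        self.free = list(range(length))
        self.used = np.zeros(length, dtype=bool)

    def take_substitution_column(self) -> int:
        if not self.free:
            raise DataError("locus saturated: no fresh columns left")
        i = int(self.rng.integers(len(self.free)))
        col = self.free.pop(i)
        self.used[col] = True
        return col

    def take_indel_region(self, length: int) -> int:
        # need the run plus a one-column buffer on each side untouched so
        # independent indel events never merge into one gap run
        candidates = []
        for start in range(0, self.length - length + 1):
            lo = max(0, start - 1)
            hi = min(self.length, start + length + 1)
            if not self.used[lo:hi].any():
                candidates.append(start)
        if not candidates:
            raise DataError("locus saturated: no room for another indel event")
        start = int(candidates[int(self.rng.integers(len(candidates)))])
        lo = max(0, start - 1)
        hi = min(self.length, start + length + 1)
        self.used[lo:hi] = True
        self.free = [c for c in self.free if not (lo <= c < hi)]
        return start


def simulate_genus(
    cfg: ScenarioConfig,
) -> tuple[dict[str, LocusAlignment], SpecimenTable, GroundTruth]:
    """Simulate one genus: alignments per locus, metadata, ground truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = dendropy.Tree.get(
        data=cfg.tree, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    tip_names = {l.taxon.label for l in tree.leaf_node_iter()}
    cfg_names = {sp.name for sp in cfg.species}
    if tip_names != cfg_names:
        raise DataError(
            f"tree tips {sorted(tip_names)} do not match species list "
            f"{sorted(cfg_names)}"
        )

    loci = list(cfg.loci)
    allocators = {lc.name: _ColumnAllocator(lc.length, rng) for lc in loci}
    roots = {
        lc.name: "".join(rng.choice(list(BASES), size=lc.length)) for lc in loci
    }

    def draw_substitutions(n: int, weights: np.ndarray) -> list[tuple[str, int, str]]:
        """n fresh substitution events distributed over loci by weight."""
        out = []
        if n == 0:
            return out
        counts = rng.multinomial(n, weights)
        for lc, k in zip(loci, counts):
            for _ in range(int(k)):
                col = allocators[lc.name].take_substitution_column()
                ref = roots[lc.name][col]
                if rng.random() < 2.0 / 3.0:  # ts:tv = 2:1
                    to = _TRANSITION[ref]
                else:
                    to = _TRANSVERSIONS[ref][int(rng.integers(2))]
                out.append((lc.name, col, to))
        return out

    weights = np.array(
        [lc.substitution_rate * lc.length for lc in loci], dtype=float
    )
    if weights.sum() <= 0:
        weights = np.ones(len(loci))
    weights = weights / weights.sum()

    # --- evolve along the species tree (preorder) --------------------------
    node_subs: dict[int, set] = {}
    node_indels: dict[int, set] = {}
    tip_node: dict[str, dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        subs = set(node_subs[id(parent)]) if parent else set()
        indels = set(node_indels[id(parent)]) if parent else set()
        blen = nd.edge.length or 0.0
        if parent is not None and blen > 0:
            for lc in loci:
                n_sub = int(rng.poisson(lc.substitution_rate * lc.length * blen))
                for _ in range(n_sub):
                    col = allocators[lc.name].take_substitution_column()
                    ref = roots[lc.name][col]
                    if rng.random() < 2.0 / 3.0:
                        to = _TRANSITION[ref]
                    else:
                        to = _TRANSVERSIONS[ref][int(rng.integers(2))]
                    subs.add((lc.name, col, to))
                n_ind = int(rng.poisson(lc.indel_rate * lc.length * blen))
                for _ in range(n_ind):
                    glen = min(int(rng.geometric(1.0 / 3.0)), max(1, lc.length // 20))
                    start = allocators[lc.name].take_indel_region(glen)
                    indels.add((lc.name, start, glen))
        node_subs[id(nd)] = subs
        node_indels[id(nd)] = indels
        if nd.is_leaf():
            tip_node[nd.taxon.label] = nd

    lineage_subs: dict[str, set] = {}
    lineage_indels: dict[str, set] = {}

    def add_lineage(label: str, subs: set, indels: set) -> None:
        lineage_subs[label] = set(subs)
        lineage_indels[label] = set(indels)

    species_order = [sp.name for sp in cfg.species]
    for name in species_order:
        nd = tip_node[name]
        add_lineage(f"modal:{name}", node_subs[id(nd)], node_indels[id(nd)])

    for name in species_order:
        for k, steps in enumerate(cfg.variant_steps.get(name, ()), start=1):
            extra = draw_substitutions(int(steps), weights)
            add_lineage(
                f"v{k}:{name}",
                lineage_subs[f"modal:{name}"] | set(extra),
                lineage_indels[f"modal:{name}"],
            )

    event_pool: dict[str, set[str]] = {}  # global label -> species allowed to use it
    for i, ev in enumerate(cfg.ils_events):
        if len(ev.species) < 2:
            raise DataError("ILS event needs at least two species")
        mrca = tree.mrca(taxon_labels=list(ev.species))
        extra = draw_substitutions(int(ev.offset_steps), weights)
        label = f"ils{i}"
        add_lineage(label, node_subs[id(mrca)] | set(extra), node_indels[id(mrca)])
        event_pool[label] = set(ev.species)
    for i, ev in enumerate(cfg.capture_events):
        if ev.locus not in {lc.name for lc in loci}:
            raise DataError(f"capture locus {ev.locus!r} not in scenario loci")
        lc = next(l for l in loci if l.name == ev.locus)
        extra = []
        for _ in range(ev.divergence_steps):
            col = allocators[ev.locus].take_substitution_column()
            ref = roots[ev.locus][col]
            to = (
                _TRANSITION[ref]
                if rng.random() < 2.0 / 3.0
                else _TRANSVERSIONS[ref][int(rng.integers(2))]
            )
            extra.append((ev.locus, col, to))
        label = f"cap{i}"
        add_lineage(
            label,
            lineage_subs[f"modal:{ev.recipient}"] | set(extra),
            lineage_indels[f"modal:{ev.recipient}"],
        )
        allowed = {ev.recipient}
        if ev.shared:
            allowed.add(ev.donor)
        event_pool[label] = allowed

    # --- assign specimens to lineages (exact designed counts) --------------
    specimen_lineage: dict[str, str] = {}
    records: list[SpecimenRecord] = []
    for sp in cfg.species:
        composition = sp.composition or (("modal", sp.n_specimens),)
        i = 0
        for ref, count in composition:
            if ref == "modal" or ref.startswith("v"):
                label = f"{ref}:{sp.name}"
            else:
                label = ref
            if label not in lineage_subs:
                raise DataError(f"{sp.name}: unknown lineage reference {ref!r}")
            if label in event_pool and sp.name not in event_pool[label]:
                raise DataError(
                    f"{sp.name}: event lineage {ref!r} not available to this species"
                )
            for _ in range(count):
                i += 1
                sid = f"{sp.name}_{i:02d}"
                specimen_lineage[sid] = label
                records.append(SpecimenRecord(sid, cfg.genus_name, sp.name))
    table = SpecimenTable(records)

    # --- realise sequences and apply dropout --------------------------------
    def realise(lineage: str, locus: str) -> str:
        seq = list(roots[locus])
        for lname, col, to in lineage_subs[lineage]:
            if lname == locus:
                seq[col] = to
        for lname, start, glen in lineage_indels[lineage]:
            if lname == locus:
                seq[start : start + glen] = ["-"] * glen
        return "".join(seq)

    seq_cache: dict[tuple[str, str], str] = {}
    alignments: dict[str, LocusAlignment] = {}
    for lc in loci:
        dropped: set[str] = set()
        spec = cfg.dropout.get(lc.name)
        if spec is not None:
            for sid in sorted(specimen_lineage):
                species = table.species_of(sid)
                p = spec.get(species, 0.0) if isinstance(spec, Mapping) else float(spec)
                if p > 0 and rng.random() < p:
                    dropped.add(sid)
        keep = [sid for sid in sorted(specimen_lineage) if sid not in dropped]
        if len(keep) < 2:  # keep the alignment analysable
            keep = sorted(specimen_lineage)[:2]
        rows = {}
        for sid in keep:
            key = (specimen_lineage[sid], lc.name)
            if key not in seq_cache:
                seq_cache[key] = realise(*key)
            rows[sid] = seq_cache[key]
        alignments[lc.name] = LocusAlignment(
            genus=cfg.genus_name, locus=lc.name, rows=rows
        )

    barcode_loci = tuple(cfg.barcode_loci or cfg.locus_names())
    gt = GroundTruth(
        genus=cfg.genus_name,
        lineage_subs={k: frozenset(v) for k, v in lineage_subs.items()},
        lineage_indels={k: frozenset(v) for k, v in lineage_indels.items()},
        specimen_lineage=specimen_lineage,
        specimen_species={sid: table.species_of(sid) for sid in specimen_lineage},
        designed_gap=dict(cfg.designed_gap),
        barcode_loci=barcode_loci,
        designed_private_percent=0.0,
        seed=cfg.seed,
    )
    gt.designed_private_percent = gt.private_percent(barcode_loci)
    return alignments, table, gt


def write_scenario(
    alignments: dict[str, LocusAlignment],
    table: SpecimenTable,
    gt: GroundTruth,
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, aln in alignments.items():
        write_alignment(aln, outdir / f"{aln.genus}_{locus}.fasta")
    table.to_tsv(outdir / "metadata.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_STANDARD_LOCI = (
    LocusSpec("matK", 800, 0.004, 0.0),
    LocusSpec("rpoC1", 508, 0.0015, 0.0),
    LocusSpec("rpoB", 349, 0.0015, 0.0),
    LocusSpec("trnH-psbA", 450, 0.015, 0.0015),
)


def preset_scenarios(seed: int = 0) -> dict[str, ScenarioConfig]:
    """Named scenario presets shaped like the qualitative genus archetypes.

    * ``lonicera-like`` — complete lineage sorting: deep interspecific
      divergence, modest intraspecific variation, no sharing.  Expected
      outcome: a clear barcoding gap for every species, all species
      monophyletic, 100 % assignment success.
    * ``salix-like`` — pervasive sharing: three common haplotypes shared
      by all four species, under 20 % of specimens on private sequences,
      no gap for any species.
    * ``gentiana-like`` — chloroplast capture: the recipient species
      carries two haplotype classes exactly 63 steps apart, the captured
      class identical to the donor's; plus an ILS pair.  No gap for
      donor or recipient.
    * ``acer-like`` — sister-pair ILS: two sister pairs each share a
      retained ancestral haplotype while non-sister species remain
      discriminated; light matK dropout.
    """
    presets = {}
    presets["lonicera-like"] = ScenarioConfig(
        genus_name="Lonisyn",
        species=(
            SpeciesSpec("alpigena", 20, (("modal", 16), ("v1", 4))),
            SpeciesSpec("caerulea", 18, (("modal", 12), ("v1", 4), ("v2", 2))),
            SpeciesSpec("nigra", 14, (("modal", 14),)),
            SpeciesSpec("xylosteum", 15, (("modal", 11), ("v1", 4))),
        ),
        loci=_STANDARD_LOCI,
        tree="((alpigena:1.0,caerulea:1.0):0.6,(nigra:1.0,xylosteum:1.0):0.6);",
        variant_steps={
            "alpigena": (1,),
            "caerulea": (1, 2),
            "xylosteum": (1,),
        },
        designed_gap={
            "alpigena": True,
            "caerulea": True,
            "nigra": True,
            "xylosteum": True,
        },
        seed=seed,
    )
    presets["salix-like"] = ScenarioConfig(
        genus_name="Salisyn",
        species=(
            SpeciesSpec("alba", 18, (("ils0", 7), ("ils1", 5), ("ils2", 3), ("v1", 3))),
            SpeciesSpec(
                "caprea", 17, (("ils0", 6), ("ils1", 5), ("ils2", 3), ("v1", 2), ("v2", 1))
            ),
            SpeciesSpec("herbacea", 17, (("ils0", 6), ("ils1", 6), ("ils2", 3), ("v1", 2))),
            SpeciesSpec(
                "reticulata", 17, (("ils0", 7), ("ils1", 5), ("ils2", 3), ("v1", 2))
            ),
        ),
        loci=_STANDARD_LOCI,
        tree="((alba:0.02,caprea:0.02):0.02,(herbacea:0.02,reticulata:0.02):0.02);",
        ils_events=(
            IlsEvent(("alba", "caprea", "herbacea", "reticulata"), 0),
            IlsEvent(("alba", "caprea", "herbacea", "reticulata"), 1),
            IlsEvent(("alba", "caprea", "herbacea", "reticulata"), 2),
        ),
        variant_steps={
            "alba": (1,),
            "caprea": (1, 2),
            "herbacea": (1,),
            "reticulata": (1,),
        },
        designed_gap={
            "alba": False,
            "caprea": False,
            "herbacea": False,
            "reticulata": False,
        },
        seed=seed,
    )
    presets["gentiana-like"] = ScenarioConfig(
        genus_name="Gentisyn",
        species=(
            SpeciesSpec("alpina", 16, (("modal", 9), ("cap0", 5), ("v1", 2))),
            SpeciesSpec("clusii", 14, (("modal", 8), ("cap0", 2), ("v1", 2), ("v2", 2))),
            SpeciesSpec("acaulis", 10, (("ils0", 6), ("modal", 4))),
            SpeciesSpec("angustifolia", 12, (("ils0", 7), ("modal", 5))),
        ),
        loci=_STANDARD_LOCI,
        tree=(
            "((alpina:1.0,clusii:1.0):0.8,"
            "(acaulis:0.25,angustifolia:0.25):1.55);"
        ),
        ils_events=(IlsEvent(("acaulis", "angustifolia"), 0),),
        capture_events=(
            CaptureEvent("clusii", "alpina", 63, locus="trnH-psbA", shared=True),
        ),
        variant_steps={"alpina": (1,), "clusii": (1, 2)},
        designed_gap={"alpina": False, "clusii": False},
        seed=seed,
    )
    presets["acer-like"] = ScenarioConfig(
        genus_name="Acersyn",
        species=(
            SpeciesSpec("campestre", 12, (("modal", 6), ("ils0", 4), ("v1", 2))),
            SpeciesSpec("platanoides", 10, (("modal", 6), ("ils0", 4))),
            SpeciesSpec("opalus", 9, (("modal", 5), ("ils1", 4))),
            SpeciesSpec("monspessulanum", 9, (("modal", 5), ("ils1", 4))),
            SpeciesSpec("pseudoplatanus", 12, (("modal", 9), ("v1", 3))),
        ),
        loci=_STANDARD_LOCI,
        tree=(
            "(((campestre:0.3,platanoides:0.3):1.2,"
            "(opalus:0.3,monspessulanum:0.3):1.2):0.4,pseudoplatanus:1.9);"
        ),
        ils_events=(
            IlsEvent(("campestre", "platanoides"), 0),
            IlsEvent(("opalus", "monspessulanum"), 0),
        ),
        variant_steps={"campestre": (1,), "pseudoplatanus": (1,)},
        dropout={"matK": 0.05},
        seed=seed,
    )
    return presets
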