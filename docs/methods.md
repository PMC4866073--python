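# Methods

This note records the models, conventions and numerical choices behind
`barcodegap`, in the order the pipeline applies them.

## Site classification (variation statistics)

Columns are classified ignoring `N` and `-` (gaps are missing data
here, not a fifth state — indel variation is scored separately during
haplotype coding): *conserved* if at most one distinct base remains,
*parsimony-informative* if ≥ 2 bases each occur in ≥ 2 sequences,
*variable-uninformative* otherwise, *excluded* if fewer than two
comparable characters remain. Percentages are reported against the
full aligned length by default, because diversity tables conventionally
cite them against "aligned length (bp)"; whether excluded columns
belong in the denominator is genuinely ambiguous, so
`--site-denominator {all,ungapped}` exposes both dialects. Reports
round to one decimal.

## Haplotype coding

A specimen's sequence is recoded as:

* **substitution characters** — one per column with ≥ 2 distinct
  non-gap symbols. `N` counts as a distinct symbol so that strict
  haplotype identity can see it; under a coded gap the state is the
  gap symbol, which is treated as missing for all step counting (the
  indel character below carries the single step).
* **indel characters** — simple indel coding: each maximal gap run
  with identical start and end boundaries is one binary
  presence/absence character, so an indel of any length is a single
  mutation step. A specimen whose own gap strictly contains the
  character's run cannot logically be scored for it and receives a
  missing state. Runs present in every row are invariant and yield no
  character.
* **structural characters** — inversions and other multi-bp events
  cannot be detected automatically from a gapped alignment, so they
  are user-annotated (TSV: `event_type, locus, start, end`, 1-based
  inclusive). The character's state is the window's sequence content;
  any two distinct states are one step apart. Window columns are
  masked from substitution characters and gap runs fully inside the
  window are suppressed, so an annotated event contributes exactly one
  step.

**Haplotype identity** is exact vector equality by default (`strict`):
two sequences differing only where one has `N` are *not* merged,
because merging on compatibility is order-dependent. The `compatible`
mode (greedy merge in sorted specimen order, missing matches anything)
is provided for sensitivity analysis. For a locus combination only
specimens sequenced at every member locus are included; dropout
therefore changes `n_sequenced` between combinations, which is why
adding a locus can lower the *percentage* identified even though, on
the common specimen set, the identified *set* can only grow (a
refinement property the test suite asserts).

Combination ranking: percent identified, ties broken toward fewer loci
and then toward larger `n_sequenced`, then name — a deterministic total
order.

## K2P distances and the barcoding gap

Pairwise deletion: sites with `-` or `N` in either sequence of a pair
are dropped for that pair only. With transition proportion P and
transversion proportion Q over the remaining sites,
`d = −½ln(1−2P−Q) − ¼ln(1−2Q)`. Pairs with no comparable sites or a
non-positive log argument (saturation) carry an explicit
undefined flag; downstream stages must drop or impute them (the
pipeline greedily excludes the specimen with the most undefined pairs
and logs it). K2P deliberately ignores coded indel characters — the
distance is substitutions-only, mirroring the standard barcoding
metric; this is a known weakness for indel-rich spacers, which is
precisely why assignment success is computed from coded haplotypes,
not distances.

Per species the gap diagnostic compares the maximum intraspecific
distance against the nearest-neighbour distance, the minimum over
other species of the *mean* cross-species distance. Species with one
specimen have an undefined maximum (reported as such, never 0).
Histogram bin width for gap plots defaults to 0.001 substitutions/site
(configurable; nothing canonical about it).

## Neighbour joining, bootstrap, monophyly

Classic Saitou–Nei agglomeration on the Q-criterion. Ties in Q are
broken by joining the closest tied pair first, then the lowest index
pair — identical sequences then group together instead of stacking
serially onto a cluster node, and the reconstruction is fully
deterministic. Negative branch estimates are clamped to zero with the
deficit moved to the sister branch. The three-taxon terminal star uses
the closed form b_i = (d_ij + d_ik − d_jk)/2.

Bootstrap resamples alignment columns (constant columns included) with
replacement, 100 replicates by default; coded indel characters are not
resampled because the tree is built from K2P, which ignores them.
Support is the percentage of replicates containing each original
bipartition. Replicates with undefined distances are redrawn up to 10
times, then counted as non-supporting. An invariant alignment yields
all-zero supports with a warning rather than pretending resolution.

Monophyly is a split-compatibility test: a species is monophyletic iff
its specimens-versus-rest split is compatible with every branch longer
than a tolerance (default 1e-5 substitutions/site). Rationale: NJ
resolves exact ties between identical sequences arbitrarily, leaving
zero-length branches (soft polytomies), and K2P non-additivity among
near-identical sequences leaves spurious branches of order p² (~1e-6
at typical within-species divergence); 1e-5 sits above both artifacts
and well below one real mutation on any realistic alignment (≥ 1e-4
for a 10 kb barcode). On a fully resolved tree with positive branches
the test reduces to the classic "some edge separates exactly this
species". Midpoint rooting is used only to report intruder specimens
readably; the test itself is rooting-free.

## Median-joining networks

All coded characters are equally weighted; edge step counts are
Hamming distances over positions where both endpoints are non-missing.
The construction iterates: build the ε-relaxed minimum spanning
network over the current node set (ε = 0 by default, matching common
practice); for every triplet of the (connected) network add its
quasi-medians — majority state per character, with all resolutions
enumerated when the three states are distinct — until no new median
appears; finally remove median vectors not on any shortest path
between observed haplotypes. Running the quasi-median step over all
triplets (the spanning network connects every triplet) makes the final
node set coincide with the brute-force quasi-median closure restricted
to geodesic nodes, which is the property the tests pin down. Links
discovered at any stage are retained, so the graph records all equally
parsimonious alternative connections and always contains a minimum
spanning tree of the observed haplotypes at ε = 0.

Quasi-median enumeration is exponential in the worst case (highly
homoplastic multistate data); generation aborts with a clear error
beyond 10,000 median nodes. Real plastid haplotype data are close to
tree-like and stay far below the cap (the bundled scenarios generate
at most a handful of medians).

## Rarefaction and correlations

Rs(g) = Σ_k [1 − C(N−N_k, g)/C(N, g)], the expected number of distinct
haplotypes in a subsample of g individuals without replacement, with
C(a,b) = 0 for a < b. g defaults to 3 — small enough to mimic typical
barcoding reference sampling. Binomials are exact integers up to
N = 1000, log-gamma beyond (exactness at realistic sample sizes,
stability beyond). Rs is non-decreasing and concave in g, equals the
haplotype count at g = N, and falls below g whenever any haplotype has
≥ 2 copies — all asserted against exhaustive subset enumeration.

Pearson correlations (sampling size vs unique sequences) use Fisher's
r-to-z: z = atanh r, SE = 1/√(n−3), 95 % CI = tanh(z ± 1.96·SE);
two-tailed normal p by default with the one-tailed value also reported,
since conventions differ between tools. |r| = 1 is reported with a
degenerate CI and p = 0; zero variance flags r as undefined rather
than raising.

## Synthetic data: what it emulates, and what it does not

The generator evolves haplotype lineages along a user-supplied species
tree: per-branch substitution counts are Poisson with rate × length ×
branch-time, transitions:transversions fixed at 2:1 so the data sit in
K2P's model class; indel events are Poisson with geometric lengths
(mean 3 bp) and occur only at loci with `indel_rate > 0`, reproducing
the indel-rich spacer vs conserved coding-locus contrast. The default
regime is infinite-sites: every substitution takes a fresh column and
indel regions are disjoint with a one-column buffer, so true pairwise
step counts are exact event-set differences and equal the coded
Hamming distances downstream — no homoplasy, by construction.

Haplotype sharing is injected by explicit events rather than simulated
coalescence: an ILS event places the common ancestor's haplotype
(optionally offset by a few substitutions, so several retained
polymorphisms can coexist) into two or more species; a capture event
builds a haplotype exactly `divergence_steps` substitutions from the
recipient's modal haplotype, concentrated on a chosen locus, and
shares it with the donor. Specimen counts per lineage are fixed
integers, not multinomial draws, so designed haplotype frequencies —
and hence designed private-specimen fractions — are met exactly on
every seed. Dropout removes whole locus rows per specimen with a
per-locus (optionally per-species) probability.

Four presets encode the archetypal outcomes: `lonicera-like`
(complete lineage sorting: gap everywhere, all species monophyletic,
100 % assignment), `salix-like` (three haplotypes shared by all four
species, 10/69 ≈ 14.5 % private specimens, no gap), `gentiana-like`
(capture with 63 designed steps plus an ILS sister pair),
`acer-like` (two ILS sister pairs, a discriminated outgroup species,
light dropout on the least amplifiable locus). Locus lengths and rates
(matK 800 bp, rpoC1 508, rpoB 349, trnH-psbA 450; substitution rates
0.004/0.0015/0.0015/0.015 per site per time unit, indels only on the
spacer) give per-branch mutation counts of realistic magnitude for
congeneric plastid comparisons.

What the generator does **not** reproduce: genuine coalescent variance
(sharing is deterministic, not a stochastic outcome of population
sizes), homoplasy and alignment error (no recurrent mutation, no
misalignment), rate heterogeneity across sites, and sequencing noise
(no ambiguity codes). Passing the end-to-end tests therefore
demonstrates that the pipeline recovers the designed evolutionary
patterns when its model assumptions hold — not that those assumptions
hold for any particular empirical dataset.

## Problem sizes and determinism

Preset genera run 52–69 specimens × 4 loci (≈ 2.1 kb concatenated);
a full per-genus pipeline with 100 bootstrap replicates takes a few
seconds, and the acceptance script's cross-checks (100 additive
matrices for NJ, all frequency partitions to N = 10 for rarefaction,
exhaustive 3-row gap masks to length 5 plus 1000 random longer ones
for indel coding, 110 random haplotype sets for network properties,
5 pipeline seeds per preset) complete in well under a minute on one
CPU. All randomness flows from explicit seeds; identical inputs and
seed give byte-identical FASTA and JSON output (reports contain no
timestamps).

## Known limitations

* Inversions must be annotated by hand; automatic coding of an
  unannotated inversion would appear as a cluster of substitution
  steps instead of one step.
* K2P distances between highly diverged sequences can saturate; such
  pairs are excluded from gap statistics (with a logged count) rather
  than extrapolated.
* The `compatible` haplotype-merging mode is order-dependent by
  nature; it is intended for sensitivity analysis only.
* The median-joining cap makes the network stage unusable for data far
  from tree-likeness (hundreds of mutually homoplastic characters) —
  by design, since the result would not be interpretable anyway.
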