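# Methods

`edibleflora` implements a biogeographic analysis pipeline for national
edible-plant diversity: checklist curation, occurrence-record cleaning,
grid-based endemism metrics, and aggregation over administrative and
ecological region polygons. This note documents the models, conventions
and design choices behind each stage, and what the synthetic data
generator does and does not emulate.

## Checklist curation

A checklist row is one accepted taxon with its family and genus, status
flags (native, endemic, naturalised, cultivated, locally reported in food
use), growth habits from a fixed five-value vocabulary (tree, shrub,
herb, climber, other), and the neglected-and-underutilized-species (NUS)
flag. Invariants are enforced at construction: endemic implies native,
and `is_nus` is always the negation of `in_crop_census`.

Name reconciliation matches verbatim names against a locally supplied
backbone table (input name, accepted name, taxon id, match status).
Matching is exact after a conservative normalization — trim, collapse
internal whitespace, case-fold. No fuzzy or phonetic matching is
performed: a fuzzy match that silently merged two taxa would corrupt
every downstream count, whereas an unmatched name is visible and
auditable. Synonyms resolve to their accepted taxon, so several verbatim
names may collapse to one taxon id. Duplicate backbone input names are
tolerated only when they agree; conflicting duplicates are a hard error.

NUS flagging is a set-membership test: a catalogued species is NUS
exactly when its accepted name is absent from the supplied crop-census
list. An empty census therefore makes every species NUS.

Percentage shares use round-half-away-from-zero to one decimal
(`Decimal` arithmetic, not binary floats, so 0.15 rounds to 0.2). This
is the convention most published one-decimal shares in this literature
follow; a few printed values in comparable tables are truncations
inconsistent with their own numerators (for example 1806/3805 printed as
47.4 where consistent rounding gives 47.5), and the test suite documents
rather than reproduces those.

Family and genus rankings count distinct genera/taxa per group, sort by
the primary count with ties broken by species count and then name, and
can be restricted to native taxa. A species with several growth habits
counts once under each habit (set semantics).

## Occurrence cleaning

Raw records keep their coordinate strings verbatim. Filters are pure
per-record predicates applied in a fixed order:

    parse -> range -> nonzero -> equal-coords -> precision ->
    centroid -> sea -> urban -> institution -> deduplicate

Each removal is attributed to the *first* failing filter, so per-filter
counts are exclusive and the report identity

    n_input = n_output + sum(removals) + n_duplicates_collapsed

holds by construction. Because every predicate is pure, the set of
surviving records is invariant under any permutation of the record-level
filters; only attribution depends on the order, which is therefore a
documented convention, not a scientific claim.

Conventions and defaults:

* **Precision** is counted on the verbatim string, trailing zeros
  included ("4.50" has two decimals), with a minimum of 3 decimals
  (~100 m at the equator). Scientific notation fails this filter. When
  only a parsed float is available the shortest round-trip rendering is
  used — a documented fallback that can undercount trailing zeros, which
  is why the pipeline preserves source text.
* **Centroid filter**: records within 5 km (default, configurable) of
  the country centroid are removed; these are records georeferenced "to
  the country".
* **Institution filter**: records within 100 m (default) of a supplied
  institution point (botanic gardens, ex-situ repositories).
* **Sea filter**: points outside the land polygon are removed; points
  exactly on the land boundary are retained (coastal specimens are
  legitimate). Urban and institution boundary points are removed. Both
  choices are conservative toward data quality and are pinned by tests.
* All distances are great-circle (haversine) on a sphere of radius
  6371.0088 km; no projection-based buffering is attempted, which at the
  sub-km buffer scales involved differs from an ellipsoidal computation
  by far less than a coordinate's third decimal.
* **Deduplication** keeps the first record per exact
  (taxon, latitude, longitude) triple. Collector and date are not part
  of the key because the analysis unit is the unique georeferenced
  record per species and location.

Out-of-range parsed coordinates (|lat| > 90, |lon| > 180) get their own
removal reason rather than being folded into parse failures, so the
audit report distinguishes malformed text from impossible coordinates.

## Grid metrics

Cells are half-open squares `[edge, edge + 0.1°)` anchored at
(-180, -90), so grids computed from different datasets align on the same
lattice. The anchor-to-global-lattice choice (rather than anchoring at
the data extent) makes cell indices reproducible across runs and
datasets. Cell assignment is floor division with a 1e-9 cell-unit snap
toward the higher cell, so coordinate strings that denote exact lattice
edges obey the half-open convention despite binary floating point; the
tests verify agreement with exact `Decimal` arithmetic on random
coordinates and on lattice edges.

Presence is binary per (species, cell); duplicate records within a cell
collapse before any metric is computed, making all metrics invariant
under record duplication. Per occupied cell:

* `SR` — species richness, the number of distinct species present;
* `WE = Σ_s 1/C_s` — weighted endemism, where `C_s` is species *s*'s
  range size in occupied cells. Inverse-range weighting is the standard
  endemism convention: a single-cell endemic contributes 1, a species
  in 100 cells contributes 0.01;
* `CWE = WE / SR` — corrected weighted endemism in (0, 1], the mean
  inverse range size of a cell's flora, highlighting concentrations of
  narrow-ranged species independent of absolute richness.

Conservation law used as a global invariant: summed over all occupied
cells, WE equals the number of gridded species, because each species
contributes `C_s × (1/C_s) = 1`. Degrees are not equal-area; 0.1° is
treated as ~10 × 10 km², an approximation that matches the standard
tooling in this literature and is acceptable within one country at low
latitudes.

Range size is defined on the same grid used for the metrics; no
independent range estimate (convex hull, SDM) is attempted.

## Regional aggregation

Regions are tiling polygon sets (departments, bioregions) loaded from
GeoJSON and validated at load: unique names, valid geometries, and no
overlapping interiors. Points on shared edges are assigned to the
alphabetically first covering region — a stable, documented tie-break
for an event the data make rare but not impossible. Records outside
every region are counted and reported, never silently dropped.

Per-region summaries count records and distinct species, genera and
families among them (zero-record regions are emitted with zeros, as a
region with no collections is itself a finding). Species breadth is the
number of distinct regions holding at least one record; headline counts
(breadth > 20, > 30, = 1, ≤ 5, = all regions) use configurable
thresholds matching the standard departmental cuts.

The sampling-effort check is an ordinary least-squares regression of
regional species richness on regional record counts, with the slope's
two-sided t-test on n − 2 degrees of freedom. Raw counts are the
default; a log-log option exists behind a flag but is not default,
because the claim being checked is a linear association. Regions with
zero records are excluded from the fit (their richness is structurally
zero), and constant record counts are a hard error.

## Synthetic data generator

The generator is first-class, tested code. Its defaults emulate the
composition of the Colombian edible flora: 73.8% native, 3.8% endemic
(a subset of natives), 11.9% naturalised (a subset of non-natives),
17.4% cultivated, 64.6% locally reported, 3.1% crop-census members, and
82.3% of species with at least one georeferenced record. Per-species
record counts follow a truncated discrete power law (default exponent
1.6, truncation 400), reproducing the stylized fact that a handful of
heavily collected species dominate the record total; range sizes follow
a truncated power law (default exponent 2.0, truncation 100 cells) from
single-cell endemics to near-landscape-wide species, grown as contiguous
cell blobs seeded near a few hotspot centres with probability 0.7.

The default landscape is a 4° × 4° extent (a 40 × 40 cell grid at 0.1°)
with a rectangular land polygon inset by 0.3° of "sea", six vertical
department strips, four horizontal bioregion strips, two urban squares
and three institution points at fixed positions, and the land centroid
as the country-centroid analogue — sized so the full pipeline runs in
seconds while every code path (sea, urban, institution, centroid,
regional tiling) is exercised.

Contamination is injected at stated per-filter rates, each contaminated
record violating **exactly one** filter by construction (base records
are sampled only from cells clear of every exclusion zone, and each
contaminant is placed to fail its target filter and no earlier one).
This makes removal attribution exactly testable against the recorded
labels; mixed-violation records are deliberately absent from the default
scenarios. Record counts per species are topped up to the drawn range
size so realized range equals drawn range — the answer key's range cells
are therefore exact, not probabilistic.

What the generator does **not** emulate: real coastline and department
geometries, spatial autocorrelation of collection effort beyond hotspot
clustering, climate-driven range shapes, taxonomic error structure
(misidentifications), or coordinate error smaller than a cell. Passing
tests therefore demonstrate algorithmic correctness and exact audit
accounting on data with the right gross statistical structure, not
robustness to every pathology of real aggregator downloads.

Determinism: all randomness flows through one `numpy.random.Generator`
seeded from the scenario seed; identical seed and configuration yield
byte-identical output files, which the end-to-end manifest verifies by
SHA-256.

## Numerical choices and degenerate inputs

* Shares: `Decimal` round-half-away-from-zero, one decimal; zero
  denominator is a hard error.
* WE/CWE: float sums checked against an exact `Fraction` oracle to
  1e-12 in tests; the conservation law is asserted to 1e-9.
* Empty inputs: empty occurrence sets yield empty metric tables and
  zeroed reports; an empty checklist is a hard error (a summary of
  nothing is meaningless); fewer than 3 regions with records is a hard
  error for the regression.
* Boundary ties: grid cells half-open toward higher indices; region
  edges to the alphabetically first region; land boundary retained, urban
  and institution boundaries removed.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run scenarios of 150–500
species (1–5 thousand records), 40 × 40 cell grids, 50-landscape
conservation sweeps, 100 injected violations per filter type, and
100-seed regression null sweeps. These sizes were chosen as the smallest
at which every distributional feature the generator models is clearly
expressed; the pipeline itself is linear in records and has been run at
hundreds of thousands of records without issue.

## Known limitations

* Equal-angle cells are not equal-area; comparisons across wide
  latitudinal spans inherit that distortion.
* No sampling-effort correction (rarefaction) of richness is applied —
  the regression quantifies the effort signal but does not remove it.
* The precision filter trusts the source's decimal rendering; archives
  that reformat coordinates upstream can inflate or deflate apparent
  precision.
* Reconciliation is exact-match only; names with orthographic variants
  beyond whitespace/case require a backbone synonym row.
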