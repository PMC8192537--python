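# Methods

## Scope and data model

`reservegap` evaluates how well a protected-area (PA) network represents a
group of species, and how efficiently, from three ingredients: per-species
occurrence records, a stack of gridded environmental predictors, and a 0/1
PA mask. All layers share one equal-area grid; cell area is a scalar in
km², coordinates are map units, and cell membership uses half-open
intervals `[x0, x0 + dx)` so rasterizing point records is deterministic.
Rasters are single-band TIFFs with the georeferencing metadata stored as
JSON in the ImageDescription tag; a write/read round trip is bit-exact.
There is no reprojection: inputs are assumed pre-registered to one grid.

The full pipeline is a pure function of (inputs, configuration, seed).
Every stage logs its in/out counts at INFO.

## Occurrence quality control

Four record-level filters run in a fixed order: (1) records flagged
unidentified at species level; (2) records sharing a grid cell with a
known country-centroid or collection-institution coordinate — a cell-level
match is the resolution-consistent analogue of a point-radius match and is
exactly testable; (3) records with coordinate uncertainty above 1 km
(records with *unknown* uncertainty are retained — unknown is not
too-coarse, and dropping them would empty most aggregated datasets);
(4) exact-coordinate duplicates within species, first record kept.
Duplicates are removed last so that a duplicated erroneous record is
attributed to its error class in the report. Duplicate matching is
within-species only; identical coordinates across species are legitimate
co-occurrence.

After cleaning, species occupying fewer than 15 distinct grid cells are
excluded from modelling; uniqueness is counted at pixel resolution, so
many records in one cell count once.

## Predictor screening

VIF_j = 1/(1 − R²_j), with R²_j from an OLS regression of predictor *j* on
all others over unmasked cells. Pruning is iterative: drop the
highest-VIF variable (ties broken against a user-supplied relevance
ranking, default input order), recompute, repeat until all VIF < 10.
Iterative recomputation (rather than removing all offenders at once) is
the standard schedule and guarantees termination in at most p steps. An
exactly collinear variable reports VIF = ∞ (R² within 1e-12 of 1).

## Distribution models

The modelling stage is the ensemble machinery, deliberately decoupled from
any particular learner. Two simple deterministic learners are built in:

* **logistic** — L2-regularized logistic regression (C = 10) on
  standardized linear + quadratic predictor terms with balanced class
  weights, the standard presence–background weighting that gives the
  presence and background sets equal total weight. Quadratic terms make
  the model well-specified for unimodal (Gaussian-like) niches.
* **envelope** — a percentile environmental envelope: per predictor the
  score is 1 − 2·|F(v) − 0.5| with F the empirical CDF of the training
  presences; the cell score is the minimum over predictors (most limiting
  variable).

Background points are drawn uniformly without replacement from the unique
occurrence cells of *other* species of the same group (target-group
background, 10,000 by default, capped at pool size with a warning). This
choice cancels shared sampling bias: presences and backgrounds carry the
same accessibility footprint. Backgrounds are drawn once per species, not
per replicate.

Each technique is fitted on 70% of presences and backgrounds (split
independently, train size = round-half-up, both sides non-empty) and
scored on the held-out 30% with the True Skill Statistic at the max-TSS
threshold. TSS = sensitivity + specificity − 1. Ten replicate splits are
averaged per technique (mean suitability, mean TSS) before ensembling.
Technique means with TSS > 0.7 are combined by TSS-weighted averaging
(weights = TSS normalized to sum 1); the ensemble TSS is the weighted mean
of its members' TSS, and a species whose ensemble TSS is ≤ 0.7 is dropped
from all downstream stages (in a live analysis it would be replaced by
another species to keep group sizes constant).

The ensemble is multiplied by exp(−d/δ), d = Euclidean distance from each
cell center to the nearest presence cell, to suppress predictions far from
the species' known area of occurrence (geographic barriers and dispersal
limits that macroclimatic models cannot see). δ defaults to 10 cell
widths; the restriction is applied to the ensemble layer, after
ensembling. The restricted layer is rescaled to [0, 1] and binarized at
the threshold maximizing TSS over a 0.01-step grid, evaluated on all
presences vs. all backgrounds; exact ties go to the lowest threshold.

## Targets, achievement, classes

The conservation target is the minimum fraction of a species' distribution
area that must be protected: 0.80 at or below 100 km² (the
critically-endangered geographic-range criterion motivates the lower
anchor), 0.05 at or above 50,000 km², loglinear in between. Both anchors
are closed so the function is total; the log base cancels in the
interpolation. Achievement = protected range area / (target fraction ×
range area), evaluated on the binarized SDM range. Classes: represented
(≥ 1), underrepresented ([0.5, 1)), neglected (< 0.5). The boundary at
exactly half the target follows the strict (< 0.5) rule; a
`neglected_inclusive` flag switches to the variant that counts exactly-half
as neglected. Extrinsic representativeness is the percent of species
represented.

## Prioritization and efficiency

Reserve selection is a minimum-cost set multicover over grid cells: unit
cost equals cell area (the efficiency questions are about *amount of
area*), per-species amounts are cell area where the binary range is 1, and
absolute targets are target fraction × range area, clamped (with a logged
warning) to the amount attainable outside locked-out cells. Exclusion
masks (e.g. degraded sites) lock cells out of every solution; a species
whose entire range is excluded is an error.

The exact solver enumerates all subsets when at most `size_limit` (15)
free units remain, choosing the cheapest and breaking ties by the
lexicographically smallest unit set. Larger instances are solved by
branch-and-bound integer programming (HiGHS via `scipy.optimize.milp`,
zero relative gap) with a geometric index perturbation (ε·2^−i, capped at
i = 40, ε = cell area/4) that steers equal-cost optima toward the
lexicographically smallest set; beyond 40 free units the tie-break is
best-effort, and determinism comes from the solver itself. The greedy
solver adds the unit with the largest shortfall reduction per cost (ties:
lowest index) and is used where exact optimality is unnecessary.

Two runs give the efficiency metrics. *Completeness* locks the PA cells in
and measures the expansion needed: completeness = 100·pa/(pa + added),
expansion = 100 − completeness. Because the expansion is also commonly
quoted relative to the current network, the report additionally carries
`expansion_of_current_pa_pct` = 100·added/pa and its complement
`completeness_alt_pct`, so both readings are available. *Specificity*
solves without constraints and reports 100·area(solution ∩ PA)/
area(solution); the solution area (not the PA area) is the denominator.

## Synthetic study systems

The generator produces fully known study systems for validation:

* **Predictors** — Gaussian-filtered white noise (σ = 4 cells) plus random
  linear gradients, orthogonalized by QR so pairwise correlation is
  exactly zero, then unit-scaled. A requested collinearity r replaces
  field j of a designated pair with r·field_i + √(1−r²)·field_j, giving an
  empirical correlation of exactly r for VIF testing.
* **Species** — suitability is a product of per-predictor Gaussian
  responses anchored at a random cell's predictor vector (peak suitability
  1 there), rescaled to [0, 1]; cells at or above the 0.5 occupancy
  threshold form the true range. A common breadth scale is calibrated by
  bisection so realized range areas follow a lognormal draw (median 1.25%
  of the domain — 12,500 km² on the default grid — log-sd 1.5), spanning
  both target anchors. Optionally only a subset of predictors is narrow
  ("limiting"); the default is isotropic.
* **Occurrences** — clean records fall in true-range cells with
  probability ∝ suitability × a smooth accessibility field (sampling
  bias), jittered within the cell, uncertainty ≤ 500 m. Errors are
  injected at configurable rates: records placed exactly at one of k
  "country centroid" coordinates (always chosen in cells outside every
  true range, so QC removal counts are exactly predictable), records with
  uncertainty in (1, 10] km, exact duplicates of a clean record of the
  same species, and records flagged unidentified. Per-record truth labels
  are returned.
* **PA networks** — a requested fraction of cells placed uniformly at
  random, biased toward a smooth remoteness field (Gumbel top-k weighted
  sampling), or constructed as the exact solver's unconstrained solution
  for a designated species subset (padded at random up to the requested
  coverage, never trimmed) — the known perfect-specificity case.

Default scenario: 100×100 grid of 10-km cells (10⁶ km², country scale),
8 predictors, 20 species, 60 records per species, error rates 5% centroid
/ 5% high-uncertainty / 10% duplicate / 5% unidentified, random PA
covering 15% of land (between typical national coverages).

## What the synthetic tests do and do not show

Validation scenarios demonstrate *internal consistency*: QC removes
exactly what was injected; the solver matches exhaustive enumeration; a PA
network built as the unconstrained optimum scores 100% on both efficiency
metrics; and on error-free, densely sampled data (150 species sharing a
background pool, 150 records each) at least 90% of the species completing
the pipeline receive the same achievement class as their true ranges give.
Species the method itself discards (below 15 unique cells, or ensemble
TSS ≤ 0.7) receive no class and are excluded from that agreement
denominator, mirroring the replace-on-discard convention of live analyses.

Real data differ in ways the generator does not emulate: niches are not
Gaussian products, predictors are collinear in structured ways, detection
varies among species, taxonomy is imperfect beyond a single flag, and PA
boundaries follow terrain and tenure rather than cells. Passing these
tests therefore shows the machinery is correct, not that any particular
empirical analysis is accurate. Class-agreement rates hover near their
asymptote only under dense sampling; sparse groups will recover classes
less reliably, which is a property of the method, not of the
implementation.

## Numerical choices and degenerate inputs

* Max-TSS threshold grid is 0.01 steps on [0, 1]; exact ties (within
  1e-12) go to the lowest threshold; all scores equal yields threshold 0
  and an all-presence map.
* TSS requires both classes; VIF requires ≥ 2 non-constant predictors and
  more cells than variables; an R² within 1e-12 of 1 reports VIF = ∞.
* The train/test split uses round-half-up with a floor of one sample per
  side; fewer than two presences is an error.
* Suitability layers are min-max rescaled over valid cells; a constant
  layer rescales to all-ones.
* Infeasible prioritization targets are clamped to availability with a
  per-species warning; a species with zero available amount raises.
* All randomness flows from integer seeds through `numpy` generators;
  species-level seeds derive from a CRC32 of the species id, so results do
  not depend on process hash randomization.

## Problem sizes used in validation

Test and acceptance runs use grids of 30×30 to 100×100 cells, 6–150
species, and solver instances up to 10,000 planning units (exact) — sizes
chosen so the full suite exercises every code path at meaningful scale
while completing in minutes on one CPU. The exact-vs-enumeration check
runs on 200 random instances of ≤ 15 free units, where exhaustive search
is feasible.

## Known limitations

* Learners are intentionally simple; boosting/forest/maximum-entropy
  learners can be plugged in but are not shipped.
* The decay constant δ is a free parameter (default 10 cells); no
  data-driven calibration is attempted.
* Lexicographic tie-breaking in the integer program is exact only for the
  first 40 free units.
* Mixed resolutions within one analysis are unsupported by design; one
  grid per run.
* The maximal-coverage variant of reserve selection (maximize targets met
  under a budget) is out of scope; the solver is minimum-set only.
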