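# Methods

This note documents the statistical content of `occscreen`: what each
heuristic computes, the conventions and defaults chosen where several
were defensible, what the synthetic generators emulate, and what the
test suite does and does not demonstrate about real data.

## Data model and filtering

All heuristics consume a validated six-field table (`species`, `x`, `y`,
`year`, `spatialUncertainty`, `identifier`). Validation is accountable:
records are never silently discarded — rows with non-finite coordinates,
negative uncertainty, missing or out-of-range years, or uncertainty above
the user threshold move to a reject table with a reason, and
`retained + rejected = input` always holds.

Conventions where the contract was open:

* **Periods** are inclusive year ranges, minimum length one year. They
  must be ascending and non-overlapping: every downstream "time series"
  treats them as a partition, and permitting overlap would double-count
  records. Overlap is a hard error rather than a silent duplication.
* **Missing years** exclude a record from all temporally split outputs
  but are counted and reported.
* **Missing identifiers** collapse to a single default group (`"all"`)
  so ungrouped datasets need no configuration.
* **Missing spatial uncertainty** survives a threshold filter by
  default (only values *known* to exceed the threshold are dropped);
  `drop_missing=True` opts into the stricter behaviour.
* **No reprojection.** Coordinates are used as supplied, and every
  distance in the package is planar Euclidean in CRS units. For lon/lat
  data spanning a large latitudinal extent this distorts distances; a
  warning is emitted, not an error, because the heuristics remain
  interpretable as relative diagnostics.

## Counts, identification and normalisation

Record and species counts are straightforward sums per (identifier,
period); empty periods report 0 rather than disappearing. Optional
normalisation divides by the per-identifier maximum across periods, so
each group's series peaks at exactly 1 — chosen over dividing by the
total because it preserves a visual anchor when groups of very different
sizes share an axis. The identification heuristic reports the proportion
of records whose species label is present; in an empty period the
proportion is missing, not zero, since "no data" is not "nothing
identified". A count mode is available for the case where proportions
fall while absolute numbers rise.

## Rarity-recording congruence

Commonness c_s = number of distinct grid cells (user resolution, canonical
origin, half-open cells) occupied by species s, a regional-occupancy
proxy. It can be computed over the whole temporal extent (default) or per
period; per-period commonness is itself affected by recording effort, so
the default keeps the denominator stable across periods. The index per
(identifier, period) is either

* `r2` — the coefficient of determination of the OLS regression of n_s on
  c_s (for a single predictor this equals the squared Pearson
  correlation; the tests verify the identity against an explicit
  least-squares fit), in [0, 1] with 1 = proportional recording; or
* `pearson` — the correlation itself, in [-1, 1].

Fewer than three species, or zero variance in either vector, yields a
missing value with a warning: a correlation of two points carries no
information. Counts are not log-transformed; both index variants measure
only the *linear* relation, so the per-species (c_s, n_s) scatter is
returned alongside the index for users to inspect for curvature.

## Spatial coverage

Records are binned into half-open, lower-inclusive square cells
`[x0 + i·res, x0 + (i+1)·res)`. The origin is the mask origin when a mask
is supplied, otherwise the coordinate minima snapped down to a multiple of
the resolution — a fixed convention that makes gridded outputs
reproducible. Two map modes: per-period record density, and one map of
the number of periods in which each cell was sampled. With a mask, in-area
cells never sampled are reported as 0, distinct from cells outside the
study area, which are absent entirely.

## Nearest neighbour index

For a group with m ≥ 2 records, the observed statistic is the mean
Euclidean distance from each point to its nearest *other* point
(duplicates allowed, distance 0 — a pattern inflated by duplicated
localities genuinely is more aggregated, so deduplication is not applied).
The CSR null is obtained by simulation: `nsim` patterns of exactly m
points uniform over the union of the mask's in-cells (cell uniform, then
position uniform within the cell — exact because cells are equal-area).

* index = d̄_obs / mean_i(d̄_sim,i); < 1 clustered, > 1 dispersed,
  ceiling ≈ 2·√(2/√3) ≈ 2.149 for a hexagonal lattice.
* CI = empirical (α/2, 1−α/2) quantiles of the ratios d̄_obs / d̄_sim,i
  (default 90 %). This distribution-free construction was chosen because
  the simulation already provides the full null spread; under CSR the
  interval covers 1 at its nominal rate by the exchangeability of the
  observed pattern with the simulated ones, which the tests confirm over
  200 replicates.
* The closed form ½√(A/m) for the CSR expectation ignores boundary
  effects and fails for irregular regions; it is used only as a test
  oracle on all-inside rectangles (where it agrees with simulation to
  within the ~1 % edge effect), never in the index.
* The index is scale-free: rescaling coordinates and mask together
  cancels in the ratio (tested exactly, shared seed).

Default `nsim` in the CLI is 99; tests and the calibration script use 199
where a published constant is being reproduced. With m ≈ 2,000 and
nsim = 199 a single index evaluation takes well under a second.

## Environmental space

Per-record environmental variables (CSV columns or values sampled from an
aligned stack of ASCII-grid rasters) are centred and scaled to unit
variance before PCA — environmental layers come in incommensurate units,
and covariance-matrix PCA would be dominated by the largest-magnitude
variable. Component signs follow a deterministic convention (the
largest-magnitude loading of each component is positive), making loadings
and scores platform-stable.

Rotation source: the background sample when one is provided (occurrence
rows are projected into the background's space, so scores do not depend
on which other periods happen to be present — tested), otherwise the
pooled occurrence rows across all periods. Per-period rotations were
rejected because they would make ellipses incomparable across periods,
which is the entire point of the display. Background and occurrences are
deliberately not pooled for the fit: the background alone defines the
available environmental space.

Each (identifier, period) group with ≥ 3 complete rows gets a Gaussian
coverage ellipse on the selected component pair: centre = mean score,
shape = sample covariance, boundary radius² = χ²₂ quantile at the coverage
level (0.95 default, so radius² = −2 ln 0.05 ≈ 5.991). The ellipse is
parametric by design, matching the normality framing of PC scores; when
scores are visibly non-normal the `as_points` mode substitutes the raw
score cloud, and per-period skewness/kurtosis of the selected scores is
reported in the metadata to help make that call. Rows with any missing
variable are excluded from fit and scores but counted per period, so
environmentally structured missingness remains visible. Zero-variance
variables are dropped with a warning. A singular score covariance yields
a degenerate (flat/point) ellipse with a warning rather than an error.

## Synthetic generators

The generators define the study conditions for every test:

* `gen_unbiased` — the clean reference: coordinates uniform over the
  extent or mask (CSR), years uniform over 1950–2019, all records
  identified to species, constant uncertainty, species drawn
  proportionally to a geometric rank-abundance series (ratio 0.9 over 50
  species — a few common species, a long rare tail, the canonical shape).
  Defaults: two identifier groups of 2,500 records on a 100×100 extent
  with seven decadal periods, the shape of a typical multi-decade,
  two-taxon aggregated download. Passing this dataset "clean" through
  every heuristic (flat counts within multinomial sampling error,
  identification proportion exactly 1, high rarity congruence, NNI ≈ 1
  with nominal CI coverage, coincident per-period environmental ellipses)
  is itself part of the acceptance suite.
* `gen_biased` — one mechanism at a time, each with a known detection
  direction: a Thomas-like parent/offspring process for clustering
  (NNI < 1), a linearly decaying identification probability, a
  rarity-oversampling exponent g reweighting species as w^(1−g)
  (weakening count–commonness congruence), and a drifting sampling
  window along x (displacing later periods' environmental ellipses).
* `gen_hex_lattice` — the maximal-dispersion oracle: every interior point
  has six equidistant neighbours at spacing d = √(2A/(√3 n)).

Every generator is a pure function of its config and mandatory seed.

What the generators do **not** emulate: real species' range structure and
environmental niches, detection/effort processes, gridded-then-pointified
coordinates, taxonomic misidentification, or spatially correlated
uncertainty. Passing tests therefore demonstrate that each heuristic
detects the mechanism it targets under controlled conditions — not that
any threshold separates "biased" from "usable" in a real dataset, which
remains a judgement for the analyst.

## Numerical and scale choices

* Nearest-neighbour queries use a k-d tree; an all-pairs brute force is
  kept in the tests as the oracle (agreement to 1e-10).
* PCA variance fractions are cross-checked against a direct
  eigendecomposition of the correlation matrix (1e-8).
* The hexagonal-lattice NNI measured on a ~2,000-point lattice with 199
  simulations lands near 2.12–2.13 rather than the asymptotic 2.149: the
  simulated null mean on a bounded square exceeds ½√(A/n) by ~1 % of
  boundary effect, which the ratio inherits. This is the behaviour of the
  simulation-based index, not an implementation error.
* The Monte-Carlo null band used for "no congruence" rarity tests
  (|r| < 0.14 at 200 species) is the 95 % band of the correlation of
  independent draws, computed by simulation (20,000 replicates) before
  being frozen into the tests.
* Test problem sizes (e.g. 5,000-record reference dataset, 199 or 99
  simulations, 200 calibration replicates, 100,000-point ellipse
  containment checks) were chosen as the smallest scales at which the
  sampling error of each check is comfortably below its tolerance.

## Known limitations

* Temporal resolution is the calendar year; intra-annual (phenological)
  bias is invisible.
* The NNI confounds sampling bias with genuine range structure when few
  species are pooled; it is most meaningful for many-species datasets.
* Euclidean-in-CRS-units distances distort lon/lat data at continental
  extents; users wanting metric NNIs should project first.
* No bias *correction* is provided (thinning, target-group backgrounds,
  occupancy models are out of scope) — these are diagnostics only.
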