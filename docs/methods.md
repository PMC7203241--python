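# Methods

This note documents the models, conventions and numerical choices behind
`cytofeat`, and what the synthetic benchmark does and does not demonstrate.

## Cleaning gates

All three gates operate on one sample at a time and are pure functions of
(values, parameters); the fitted parameters are recorded in the gate audit
so any gate can be replayed.

**Singlet gate.** Pulse area grows roughly twofold when two cells pass the
laser together while pulse height grows much less, so singlets lie on a line
through the origin in (area, height). The gate fits that line robustly and
keeps events with |residual| ≤ `band_factor` · 1.4826 · MAD(residuals),
i.e. `band_factor` robust standard deviations (default 2.5, which keeps
≈98.8% of Gaussian-residual singlets). The default zero-intercept fit uses
the median of per-event height/area ratios — the Theil–Sen estimator for a
line constrained through the origin, exact in O(n log n) and insensitive to
up to 50% aggregate contamination. With `fit_intercept: true` the
unconstrained Theil–Sen slope/intercept is estimated on a deterministic
even-stride subsample of ≤2000 events, since the full pairwise-median
estimator is quadratic in the event count.

**Density gates (debris, live).** Both reuse one primitive: a Gaussian KDE
(Silverman's rule bandwidth × a configurable multiplier, default 1.0)
evaluated on an evenly spaced grid of 512 points spanning the data range.
The two highest local maxima are taken as the population modes; the
threshold is the grid point of minimum density strictly between them, with
the leftmost point winning ties, so the gate is fully deterministic. The
debris gate keeps the high-scatter side of the valley on scatter area
(leukocytes are large); the live gate keeps the dye-negative (low) side of
the viability channel. Side selection is explicit config with those
defaults. A unimodal channel raises a "no valley" error carrying the single
mode location; an optional per-gate `fallback_quantile` converts that into
a plain quantile cut, recorded as such in the audit.

Gate order is fixed — singlet → debris → live, each on the survivors of the
previous — and individual gates can be disabled but not reordered; this
keeps the audit semantics (each gate's n_in is the previous gate's n_kept)
unambiguous.

## Thresholds

The FMO control for marker *m* is stained with every marker except *m*, so
its *m* values are all true negatives. The positivity cutoff is the
empirical q-quantile (default q = 0.99) of those values after the same
cleaning chain applied to samples; the 1% headroom absorbs stray debris
noise that survives cleaning. Quantiles use linear interpolation between
order statistics (numpy's default): for sorted x₍₁₎…x₍ₙ₎ the q-quantile
sits at position 1 + q(n−1), so values 1…100 at q = 0.99 give 99.01. The
convention, q, and the event count used are recorded per marker.

Two consequences worth stating plainly:

- By construction ~(1−q) of truly negative events exceed the threshold per
  marker, so a population whose pattern has k negative markers retains only
  ≈ q^k of its cells under exact-pattern counting (k = 4 → ≈96%). This is a
  property of the quantile rule itself, not an estimation error, and it
  bounds the accuracy of exact-pattern abundances.
- Threshold comparison is strict (> is positive, equality is negative),
  because the quantile is defined as the upper envelope of the negative
  population. `binarize_ge` provides the inclusive variant.

Without an FMO, a marker with well-separated negative/positive modes is
thresholded by the same density-valley primitive on the (transformed)
pooled cleaned sample values. Resolution precedence per marker is manual
override > FMO quantile > sample valley; an unresolvable marker is a
configuration error listing the routes tried.

## Phenotyping

Marker order is fixed by the panel config and shared experiment-wide. Each
event's bit pattern is packed into an integer code and counted per sample;
a phenotype exists if at least one cell in at least one sample carries it,
and every (sample, phenotype) pair gets an explicit row (zero-filled where
absent) so correlation and regression see complete grids. Percentages
always use the sample's cleaned event count as denominator — never the
filtered subset — so filters change which rows are shown, not their values.

The abundance filter keeps a phenotype iff it satisfies all marker
constraints and its percent strictly exceeds `min_percent` in ≥1 sample
("greater than" is read strictly); `min_count` adds a rare-population
rescue (max count ≥ min_count in any sample). Lineage/subset/resident
labels come from ordered first-match-wins rules; unmatched phenotypes get
the default label ("unknown"). Population ids are assigned densely by
(lineage label in config order, then descending mean percent, then
bitstring) — deterministic, but not intended to match any external
numbering.

## Statistics

- Correlation between populations: Pearson on per-sample percent vectors by
  default (Spearman by config); zero-variance populations yield missing
  (NaN) entries, never imputed zeros.
- Outcome association: per population, OLS of the external measurement on
  the percent (the direction mirrors regressing a burden measurement on
  population size; no causal claim). Slope, intercept, r² (squared sample
  correlation), two-sided t test of zero slope, and the t-based CI. A
  constant outcome yields slope 0/r² 0; a constant predictor yields an
  undefined (NaN-flagged) result.
- Multiple testing: Benjamini–Hochberg step-up by default, Bonferroni and
  Benjamini–Yekutieli available; adjustment is opt-in and raw p values are
  always kept alongside.
- Group comparison: Welch's unequal-variance t test per timepoint by
  default (Student's by config), significance flagged at α = 0.05.
- Manual-gating validation: Spearman ρ with two-sided p and mean absolute
  difference in percentage points over matched (sample, phenotype) pairs;
  unmatched manual rows are listed and excluded.

`slope_ci_coverage` is a built-in calibration harness: it plants one linear
outcome model among null populations, runs the association stage, and
reports 95%-CI coverage and the BH false-discovery proportion among nulls.
At the defaults (n = 10 samples, slope −0.8, noise sd 0.1, 7 nulls) the
interval is calibrated: 95.2% coverage over 4000 simulations.

## Synthetic experiments

The generator emulates, on the analysis scale, exactly the structure the
method assumes:

- each marker is a two-component Gaussian (negative N(1, 0.3²), positive
  N(4, 0.3²) by default — 10σ separation, comfortably past the 6σ
  "well-separated" regime);
- six planted phenotypes over an 8-marker T-cell-style panel, with base
  weights 0.28/0.16/0.18/0.14/0.12/0.07 (normalised) and per-sample weights
  drawn Dirichlet with concentration 250 (sd ≈ 2–3 percentage points for
  the larger populations — modest biological variation);
- singlet scatter on a height = 0.9·area line with 2% relative height
  noise; doublets as two-cell area sums at single-cell height; debris at
  low area (N(8000, 2000²) vs N(50000, 5000²) for cells); dead cells
  bright on the viability dye; artifact fractions 0.05/0.10/0.10;
- one FMO per marker: a full sample with that marker forced to its
  negative component;
- outcome = 5 − 0.8 · (true percent of the planted population) + N(0, 0.1²).

Two structural choices make the benchmark interpretable rather than easy:
planted bit patterns are pairwise Hamming distance ≥ 2, so a single
false-positive marker call can never convert one planted phenotype into
another (spurious patterns are always non-planted and stay below the 0.5%
filter at these weights); and the outcome-planted population carries a
single negative marker, so the association check measures the regression
machinery rather than the deterministic ≈1%-per-negative-marker retention
loss of the quantile rule — that loss is measured separately by the
percent-error check, where it is the dominant error term (≈0.7–0.9 pp for
the second-largest population, close to the 1.0 pp recovery tolerance; the
tolerance is met but not by a wide margin, and that is a faithful picture
of the method's exact-pattern accuracy under a 99% threshold).

What passing the synthetic suite does **not** show: robustness to
compensation/unmixing error (inputs are assumed compensated; spillover is
emulated only as an optional additive nuisance), to heavy-tailed or skewed
marker distributions, to drifting acquisition (no time channel), or to
panels whose positive/negative modes overlap. Real-data thresholds from
density valleys also depend on the KDE bandwidth rule where modes are
unbalanced; the multiplier is exposed in config for that reason.

## Numerical and engineering choices

- FCS support is a minimal, self-contained reader/writer for 3.0/3.1
  list-mode (float/double/integer, both byte orders); the writer emits
  float32 little-endian 3.1 and exists for fixtures and synthetic data.
  $SPILLOVER is deliberately not applied.
- Default transform is identity (already-unmixed data); arcsinh with
  configurable cofactor (default 150) for conventional-cytometer data.
- CSVs are written at full float precision and read back with round-trip
  float parsing, so stage outputs are bit-stable across re-runs and the
  staged CLI path equals the in-memory path.
- Every output table carries the SHA-256 config hash in a header comment;
  identical (inputs, config, seed) reproduce identical bytes.
- Degenerate inputs have defined behaviour throughout: constant channels
  raise "no valley" errors (with optional quantile fallback), empty
  population tables draw empty figures with a warning, zero-variance
  vectors yield flagged-missing statistics.

## Problem sizes used in the checks

The acceptance checks run the default conditions (10 samples × 50,000
events, 8 FMOs × 20,000 events) end to end — about half a minute on one
CPU; the unit suite uses the same generator scaled to 4 samples × 8,000
events. Calibration checks use 1000 simulated association experiments and
20 seeded 20,000-event mixtures for the valley gate.
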