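# Methods

This note documents the models and procedures implemented in `accelharm`,
the defaults chosen where the design was open, and what the synthetic-data
tests do and do not establish about real data.

## Epoch measures

All four measures are computed per calendar minute aligned to :00 seconds,
from contiguous tri-axial acceleration in g (nominally 80 Hz, ±8 g dynamic
range). Partial boundary minutes are omitted.

**ENMO.** Mean over samples of max(‖a‖ − 1, 0), in g. Computed on
autocalibrated data; MIMS, MAD and AI are computed on uncalibrated data,
mirroring the split in the reference tooling where only the ENMO pipeline
calibrates. With an identity calibration the two conventions coincide.

**MAD.** (1/n) Σ |rᵢ − r̄| over the minute, in g; undefined (missing) for
fewer than 2 samples.

**AI.** The minute is divided into sub-epochs of `sub_epoch_s` (default
1 s). Per sub-epoch, AI_sub = √(max(⅓ Σₘ (σ²ₘ − σ̄²), 0)), with per-axis
variances computed with the unbiased (n−1) estimator, and σ̄² the device's
systematic noise variance (default 0; can be set to the median per-axis
variance over detected still windows). The minute value is the sum of the
sub-epoch values. Sub-epochs with fewer than 2 samples contribute 0 with a
warning.

**MIMS.** Per axis: (1) linear interpolation to `resample_hz` (default
100 Hz); (2) replacement of dynamic-range-clipped runs by a local quadratic
fitted through 3 neighbor samples on each side, capped in magnitude at
1.5× the dynamic range and never below the recorded clipped value — a
deliberate simplification of the reference spline-extrapolation scheme,
switchable off; (3) zero-phase Butterworth band-pass (order 4, 0.2–5 Hz);
(4) rectification; (5) trapezoidal integration over the minute with time
in seconds (so the axis value is in g·s, which puts realistic daily sums
in the thousands); (6) truncation to 0 below `truncation_threshold`
(default 1e-4). The minute MIMS is the sum of the three axis values. The
chain interpolate→filter→rectify→integrate is positively homogeneous of
degree 1, which the tests verify numerically on in-band sines.

**Autocalibration.** Non-overlapping 10-s windows with per-axis SD below
13 mg are "still"; their mean vectors should lie on the unit gravity
sphere. Per-axis gains and offsets are estimated by iteratively regressing
each axis of the corrected points onto the closest point on the sphere
(the corrected vector scaled to unit norm), composing the affine updates
until the mean | ‖a‖ − 1 | residual stabilizes. If no still windows are
found, or the still means do not reach beyond ±0.3 g on every axis
(insufficient orientation variety — e.g. a device that lay flat the whole
time), the identity model is returned with a warning rather than an
ill-posed fit.

## Quality control

Three per-minute flags mark patterns unlikely to be human movement; they
are deliberately not a nonwear detector. A minute is flagged when any
sample in it participates in the condition, and `qc_invalid` is their OR:

- **clipped-sustained**: any axis within `clip_tol_g` (0.05 g) of the
  dynamic range for ≥ `clip_run_s` (2 s);
- **stuck values**: the identical (x, y, z) triplet repeated for
  ≥ `stuck_run_s` (1 s);
- **spike**: a sample-to-sample change above `spike_g` (11 g) on any axis.

The thresholds are all configurable; the defaults are the package's own
choices in the spirit of the national-survey QC protocols this family of
flags descends from. Flag computation is verified against a brute-force
per-sample scan on short signals.

## Minute-level preprocessing

- **Wear**: a minute is nonwear iff it lies in a maximal run of
  consecutive zero-count minutes of length ≥ 90. Missing counts are
  treated as zero for run detection (logged). The literal rule is the
  default; an optional tolerance bridges isolated nonzero "artifactual"
  runs of ≤ k minutes inside a zero run, off by default.
- **Valid minute**: wear ∧ ¬qc_invalid.
- **Valid day**: a 1440-minute calendar day (12:00 AM–11:59 PM, local
  clock, no timezone arithmetic) with at most 144 invalid minutes (10%).
  Days are completed to 1440 slots on read; absent minutes count as
  invalid, so partial first/last days are penalized for what is missing.
- **Retention**: participants with ≥ 3 valid days are kept, and only
  their valid days are carried forward.
- **Winsorization**: per measure, values above the cohort-wide 0.999
  quantile are replaced by it, pooling all retained participant-minutes
  (a single measure-specific cap). The cap is the order statistic at the
  ceiling index rather than the interpolated quantile: interpolation
  would make repeated winsorization drift downward, while the order
  statistic makes the operation exactly idempotent; at q = 0.999 on
  cohort-sized samples the difference is negligible.

## FPCA imputation

Each participant's days form a day × 1440 matrix per measure with missing
entries at invalid minutes. The smoother is a basis-projection FPCA:

1. a smooth mean-of-day curve is fitted to the pooled observed entries by
   penalized cubic spline (GCV);
2. each centered day is projected onto a 30-function cubic B-spline basis
   over minute-of-day, with a second-derivative penalty and per-row GCV;
3. the eigenproblem of the coefficient covariance is solved in function
   space (whitened by the basis Gram matrix), giving smooth, grid-
   orthonormal eigenfunctions;
4. the number of components K is the smallest K ≤ `k_max` (10) explaining
   ≥ `pve` (0.95) of the projected variance — K = 0 when rows are
   essentially identical;
5. per-day scores are re-estimated by least squares on that day's observed
   minutes only, and the smooth surface is mean + scores·φ.

Rows with under 50% observed entries are excluded from steps 2–4 and
reconstructed afterwards from the mean and their projected scores
(logged). Invalid minutes are then replaced by the smooth surface floored
at 0; valid minutes are never modified. Eigenfunctions are estimated per
participant (across that participant's days), not cohort-wide, and the
minute-of-day grid is treated as non-periodic. Participants contributing a
single day fall back to a penalized-spline smooth of that day.

## Harmonization

The mapping measure = f(AC) is a penalized regression spline: a cubic
B-spline basis of dimension 30 with interior knots at count quantiles
(serving as the cubic regression spline), a second-derivative roughness
penalty (null space: linear functions, so λ→∞ recovers the least-squares
line), and λ minimized by GCV over a log-spaced grid 1e−7…1e7 (43 points);
K-fold CV is available as an option. AC = 0 minutes are excluded from
fitting — zero counts are so frequent that they would dominate the
low-count region — but zero counts are still mapped at prediction time.
An optional seeded uniform subsample caps the fitting set; the default is
exact full-sample fitting.

Fitted values are tabulated on a 2,000-point log-spaced count grid from
the smallest positive fitted count to the largest (resolving the strong
curvature at low counts). Monotonicity is not constrained in the fit; for
inversion the grid values are projected onto the nondecreasing cone by
isotonic regression, with a warning reporting the magnitude of any
correction, and f⁻¹ is a linear-interpolation table lookup: values below
f(g₁) map to count 0, values above f(g_M) clamp to g_M with a flag.
Count cut-offs (e.g. 1853 / 2860 / 3940) translate to measure cut-offs as
f(cut-off). Predictions outside the fitted count range clamp to the
endpoints and are flagged. The fit is cross-checked in the test suite
against an independent reference GAM implementation (R mgcv, cubic
regression splines, k = 30) on common data.

## Evaluation

- **Correlations**: participant-specific Pearson r between minute counts
  and a measure, over valid minutes; degenerate series yield missing r.
  Cohort summaries via intercept-only OLS and an adjusted OLS on age, BMI,
  and sex (female as reference), with α = .05 flags.
- **Total-count errors**: per day, e_d = 100·(T̂_d − T_d)/T_d with T̂_d the
  sum of inverse-mapped measure values over the (imputed, gap-free) day.
  MPE/MAPE/MdPE/MdAPE are computed per day then aggregated within
  participant (the per-participant-total variant is available as an
  option), and across participants as mean (SD). Zero-total days are
  excluded and logged.
- **Cut-off classification**: per participant, the 2×2 table of
  (AC > cut-off) vs (ÂC > cut-off) over valid minutes, with strict
  inequalities and the positive class above the cut-off.
- **Median curves**: per age group (<60, 60–67, 68–74, ≥75 by default),
  the per-minute-of-day median over all participant-days of counts and of
  inverse-mapped counts, each smoothed by a penalized cubic spline with
  GCV (the smoother is the package's choice; any linear smoother
  preserves the constant-scaling property the tests rely on). The curve
  MAPE is 100·Σ|â − a| / Σa pooled over minutes and groups.

## Synthetic data

The generator defines the study conditions for all tests. Raw signals are
gravity (a slowly drifting unit vector) plus a bout-dependent band-limited
(0.5–3 Hz) oscillation and white sensor noise, with scheduled clipping
runs, stuck runs, and rail-to-rail spikes. Minute-level cohorts draw
counts from a zero-inflated gamma process whose activity probability
varies by hour of day (morning and late-afternoon peaks), insert nonwear
blocks as ≥ 90-minute zero runs (plus shorter sub-threshold zero runs that
must remain wear), and link each measure to counts by a strictly
increasing power law g(AC) = a·AC^p with multiplicative Gaussian noise
(CV 0.15) and small positive noise at AC = 0. The default exponents
(0.88–0.93) and coefficients give concave mapping shapes and daily-sum
magnitudes of the order observed in real wrist cohorts (counts in the
millions, MIMS/AI in the thousands, ENMO/MAD in the tens). All randomness
flows from a single seed through spawned per-(participant, day) PCG64
streams, so outputs are bit-reproducible.

What passing tests show: the pipeline's rules, formulas and fits are
implemented correctly, thresholds behave exactly at their boundaries, and
the harmonization machinery recovers a known monotone mapping under
heteroscedastic noise. What they do not show: that real wrist data follow
a power-law count↔measure relation, that the QC thresholds match any
particular device's artifact distribution, or that the imputation model
captures real behavioral variability — the generator has no
autocorrelated bout structure at the minute level and no demographic
dependence of activity.

## Numerical choices and problem sizes

- Penalized-spline systems are solved by Cholesky factorization with a
  tiny diagonal jitter; GCV = n·RSS/(n − edf)² with edf the trace of the
  hat matrix.
- Inverse lookups break exact ties in the monotonized table with an
  epsilon ramp so interpolation is well posed.
- Quantile-knot construction deduplicates knots, shrinking the basis on
  data that cannot support 30 distinct quantiles.
- The acceptance script runs 96 participants × 6 days (≈ 830k minutes,
  ≈ 280k fitted pairs per measure); the test suite uses smaller cohorts
  (8–30 participants) and 50,000-pair harmonization fits. These sizes were
  chosen to make the full pipeline cheap to re-run while keeping the
  fitted-pair counts large enough that spline recovery is limited by the
  model, not by sampling noise.

## Known limitations

- The MIMS implementation follows the published pipeline's structure but
  is not a port of the reference package; its clipped-run extrapolation is
  a documented simplification, and absolute values should not be compared
  against reference-package output to more than order of magnitude.
- The wear detector implements the literal consecutive-zeros rule; the
  allowance-window variants of published wear algorithms are only
  approximated by the artifact-tolerance option.
- FPCA imputation is per participant; participants with few days get
  little smoothing strength, and a single-day participant falls back to a
  within-day smooth.
- Harmonization maps each measure to counts; measure-to-measure mappings
  are composable through counts as a pivot but are not fitted directly.
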