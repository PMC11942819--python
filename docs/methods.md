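# Methods

This note documents the models implemented in `liftpattern`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Coordinate and measurement conventions

Trajectories are 2-D sagittal-plane bar-marker positions in centimetres,
`y` up, `x` anterior, sampled at 30 Hz by default (consumer video). Every
trajectory is rebased so its first sample is the origin, matching the
capture convention of placing the coordinate origin at the marker centre
at the start of the upward movement. Camera calibration is reduced to a
user-supplied scale factor (cm per file unit); lens and parallax
correction are out of scope.

Displacements are signed differences `Δx = x_f − x_i`, `Δy = y_f − y_i`.
A repetition's ascending phase is found on the smoothed vertical signal
(centered moving average, default window 5 samples ≈ 0.17 s): it runs
from a local minimum to the following local maximum, where extrema are
strict sign changes of the first difference. Candidate ascents with a
rise below 20 % of the largest detected rise are discarded as
tracking-noise wiggles; this threshold is irrelevant for clean signals
and makes segmentation robust to millimetre-scale jitter. How repetition
boundaries were located in the original recordings is not documented
anywhere we know of; this extremum rule is this package's construction.

`dx_max`/`dy_max` are maxima of |coordinate − segment start| over the
ascending segment. The subject reference **MMD0** is the arithmetic mean
of the three no-load maxima per axis, with a time-normalized mean
trajectory (linear interpolation onto `N = 101` points of normalized
time, the conventional 0–100 % movement-cycle grid).

## Morisita–Horn index for trajectories

The index is computed in its standard abundance form with sample totals
`X = Σx_i`, `Y = Σy_i` (the variant that uses species counts for `X, Y`
degenerates for continuous data). The inputs are the reference's and the
execution's resampled displacement sequences along the analysis axis,
each shifted to be nonnegative by subtracting its minimum — the index
needs abundance-like (nonnegative) vectors, and the shift preserves the
sequence's shape. Two consequences worth knowing:

* the index is invariant to proportional rescaling of either sequence,
  so a uniformly larger execution scores 1.0 — amplitude changes are the
  deviation measure's job, shape changes are the index's;
* localized shape distortions (e.g. a mid-lift bump) reduce the index
  monotonically with the distortion's size (verified by property test).

Which exact vectors the original analysis fed to the index is not
documented; published index values are therefore treated as dataset
inputs downstream, never as quantities this package re-derives from
trajectories. The denominator is evaluated as `Σx²·(Y/X) + Σy²·(X/Y)`,
algebraically identical to the textbook form but exact for identical
inputs and safe from under/overflow in `X²`. Floating-point overshoot
beyond [0, 1] of at most 1e−12 is clamped.

## Quadratic trend and ANOVA

The deviation–similarity trend is OLS on the basis {dev², dev, 1}
(statsmodels), reported with R² and the Pearson correlation of observed
vs fitted (equal to +√R² with an intercept). On the bundled 30-pair
dataset the fit is `y = −3.1026e−5·x² − 4.1535e−4·x + 1.0013` with
R² = 0.927.

One-way ANOVA uses the classical between/within decomposition (scipy's
`f_oneway`), with Tukey HSD adjusted p-values from the studentized-range
distribution; unequal group sizes use the Tukey–Kramer harmonic-mean
correction (equal-n designs are unaffected). `anova_from_summary`
reconstructs SSB from (mean, n) and SSW from (n−1)·SD², giving an F
identical to the raw-data computation — useful for checking published
group summaries. No Welch correction is applied, matching the plain
one-way design the summaries come from. For the published vertical
displacement summaries (56.8 ± 7.7, 59.6 ± 8.5, 64.0 ± 9.0 cm at
n = 10), this yields F(2, 27) ≈ 1.86, p ≈ 0.18 — the often-quoted
p = 0.002 for the 0 % vs 50 % contrast is not derivable from those
summaries alone and presumably reflects a repeated-measures analysis of
the raw data, which this package does not have.

## Sugeno fuzzy scoring

A zero-order Takagi–Sugeno system with two inputs:

* **deviation** (cm), universe [0, 25], six Gaussian membership
  functions named *very low* … *high*, centers at 0, 5, …, 25 cm.
  The common sigma defaults to 5/(2√(2 ln 2)) ≈ 2.123 cm so adjacent
  functions cross at membership 0.5 — the standard even-partition
  choice when the original widths are unknown. Deviations above 25 cm
  clamp to 25 (the declared maximum of the deviation scale).
* **load** (% body weight), three Gaussians at 0, 25, 50 with sigma
  10.6. The load input is retained even though only the 50 % load shows
  significant pattern change; its role is to let low loads score near 1.

The full 6 × 3 rule grid gives 18 rules; rule strength is the product
t-norm (the common Sugeno default; the original t-norm is undocumented),
and the crisp output is the activation-weighted average of the rule
constants, hence always a convex combination of them.

**Default constants.** Rule (dev level j, load level l) is seeded with
the quadratic trend evaluated at `center_j · load_l / 50`, clamped to at
most 1 — so the no-load column scores ≈ 1 and the 50 %-load column
follows the trend. Constants are validated to lie in
[0.96, 1.0013] (output range floor minus 0.01, trend intercept above).

**Calibration.** Because the Sugeno output is linear in its constants,
the constants can be re-estimated from observed (deviation, MH) pairs at
one load by linear least squares on the normalized rule-activation
basis. The other load columns keep their default proportion to the
same-row calibration constant, and those proportions are folded into the
design matrix — the problem stays linear and the calibrated system
reproduces the least-squares fit at the calibration load exactly. A
singular basis (deviations that never excite some membership function)
raises a calibration error rather than returning wild constants. On the
bundled 30 pairs the calibrated system reaches R² = 0.950, slightly
above the quadratic trend (a least-squares projection onto a basis that
can represent the trend cannot do worse).

**Categories.** Five labels (*Total Error*, *Medium Error*, *Average
Execution*, *Medium Accuracy*, *Total Accuracy*) partition the output
range [0.97, 1.0]. The original cut points are unpublished; the default
is five equal-width bins (0.006 wide), configurable, with scores below
0.97 falling into *Total Error*.

## SVR benchmark

Six presets named after the point-and-click regression tools they mimic:
polynomial kernels `(1 + x'z)^d` of degree 1–3, and Gaussian kernels
with scale √P/4, √P, 4√P for P predictors (ratio 1:4:16). Box constraint
IQR(y)/1.349, epsilon tube IQR(y)/13.49, predictors standardized on each
training fold; a kernel scale s maps to the RBF coefficient γ = 1/s².
The single predictor is the absolute deviation. Cross-validation uses
seeded shuffled 5-fold partitions shared across presets; R² and Pearson
r are computed on the pooled held-out predictions (SST about the overall
mean), and stochastic results are reported as means over ≥ 20 seeds.

On the bundled pairs the coarse-Gaussian preset averages CV R² ≈ 0.85
and the linear preset ≈ 0.86 — both near the quadratic trend's ceiling,
with linear and coarse Gaussian trading the best RMSE from seed to seed.
Published benchmarks of the same data report a larger gap (coarse
Gaussian 0.81, linear 0.72) with a coarse-Gaussian Pearson r of 0.79;
those values depend on a single undocumented fold partition and tool
internals, and are not reproducible in expectation under the preset
definitions above. This implementation's presets are stated exactly so
its numbers are reproducible; none of them were adjusted to match the
published table.

## Synthetic data

`simulate_curl` emulates a marker-tracked standing curl: within a
repetition of phase u ∈ [0, 1] the arc parameter s(u) = (1 − cos 2πu)/2
sweeps up and back down (velocity vanishes at the turning points), and
the bar sits on the circular arc x = A_x sin(πs), y = A_y(1 − cos πs)/2
— the fixed-elbow geometry with the forearm as radius. Defaults are
chosen to sit in the regime of real recordings: 30 Hz, 4 s cadence,
30 cm forearm, no-load amplitudes A_y = 56.8 cm and A_x = 23.7 cm (the
observed no-load group means), vertical gain 1.00/1.05/1.13 for
0/25/50 % load (the observed ≈ 13 % inflation at half body weight).
Noise has two parts: white positional jitter (default SD 0.2 cm,
roughly pixel-level tracking error at typical scale factors) and a slow
horizontal sinusoid for postural sway (default SD 0.5 cm). `make_study`
adds subject-level variation (forearm N(30, 2) cm, loaded gains
perturbed by N(0, 0.02)) and simulates three one-repetition executions
per load per subject; the programmed per-repetition maxima are returned
as ground truth.

What the generator does **not** emulate: trunk/elbow kinematics beyond a
fixed-radius arc, fatigue drift across repetitions, marker dropout,
occlusion, or perspective error. Passing tests on synthetic data
therefore demonstrate that the pipeline recovers programmed amplitudes,
repetition structure, and load effects under realistic noise — not that
the method generalizes across real lifters or camera setups.

## Package design

The three data-fitted analyses (quadratic trend, fuzzy scoring, SVR
benchmark) are exposed as statsmodels-style Model/`fit()`/Results objects
with `summary()` tables, because each is genuinely an estimator fitted to
(deviation, MH) pairs; the measurement plumbing around them — trajectory
IO, segmentation, the synthetic study, the CLI — stays functional, since
those stages transform data rather than estimate parameters.

## Numerical and degenerate-input policies

* A constant target makes R² and Pearson r undefined; both are returned
  as NaN and never silently zero. Degeneracy is detected with a relative
  1e−12 tolerance, not exact equality.
* `MMD0 = 0` leaves the relative deviation NaN; the absolute deviation
  is still returned.
* Repetition counts below the requested number raise a segmentation
  error naming the count found; indices are 0-based and segments
  half-open, so segments concatenate without overlap.
* All stochastic stages (fold partitions, the generator) take explicit
  integer seeds and are bit-reproducible under a fixed seed.

## Problem sizes

The bundled dataset has 30 (deviation, MH) pairs (10 volunteers × 3
executions at 50 % load). Test-suite simulations use studies of 2–10
subjects at 30 Hz with one 4-second repetition per execution, and
Monte-Carlo checks use 20 fold partitions (SVR) and 50 generator seeds
(parameter recovery) — sizes at which every quantity this package
reports is stable to well within the tolerances quoted above.
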