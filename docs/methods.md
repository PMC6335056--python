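# Methods

This note documents the models the package implements, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the design decisions taken where more than one
reasonable construction existed.

## Shape stimuli

Stimuli are simple closed shapes described at two levels: a list of
boundary elements (normalized curvature, angular position) consumed by
the tuning model, and a radial profile r(θ) used for rasterization.
Shapes are radial harmonic curves r(θ) = b + Σ_m a_m cos(m(θ − φ_m)), so
boundary descriptors are analytic rather than estimated from pixels:
curvature comes from the polar-curve formula
κ = (r² + 2r′² − r·r″) / (r² + r′²)^{3/2} evaluated on a fine (0.5°)
angular grid, and angular position is the sample angle itself.

*Curvature normalization.* Raw curvature (units 1/radius, with the big
reference circle at radius 1) is mapped to [−1, 1] by c = κ/(1+|κ|).
This places the unit circle at +0.5, sends sharp convexities toward +1
and sharp concavities toward −1, and is exposed as a configuration point
rather than hard-coded doctrine, since only the range of the normalized
axis is canonical.

*Sampling.* Descriptors are taken at the local curvature extrema of the
profile plus 50 uniformly spaced boundary points (`sampling="both"`,
the default); either set alone is available, because whether an element's
angle refers to a generic boundary point or to a curvature extremum is a
genuine modeling choice.

*Rotations and bank size.* Each base shape is rotated in 45° steps; the
number of distinct rotations follows from the harmonic content (distinct
rotations = 8/gcd(g, 8) for harmonic-order gcd g), and the default
51-shape bank — two circles plus 41 eight-rotation and 8 four-rotation
shapes — expands to the standard 362 stimuli. Shape amplitudes are capped
so every shape is strictly smaller than the big circle, which therefore
defines the bank's pixel scale (`size_px`, default 32, is its diameter).

*Rasterization.* Binary white-on-black fill (background exactly 0,
foreground exactly the amplitude, no anti-aliasing) into a 227 × 227
field, placed by polygon area centroid; pixel coordinates are 0-based
(row, col) with 0° pointing rightward and angles counterclockwise.
Integer-pixel translation of a rendered stimulus is exact, which the CRF
sweep exploits.

## APC model and grid fitting

The response model and the fit ranges are given in the README. Choices
worth recording:

- **Angular wrapping.** Δa = min(|a − μa|, 360 − |a − μa|); circular
  distance is the only convention consistent with angular tuning.
- **Tie-breaking.** Equal-r candidates resolve to the first in
  lexicographic grid order (μc, σc, μa, σa; last axis fastest), making
  fits deterministic.
- **Scale.** Pearson r is invariant to k, so candidate selection uses
  unit-scale predictions; k is then a no-intercept least-squares scale.
  A negative k (possible for signed artificial responses) is flagged as
  degenerate rather than clamped.
- **Significance.** Two-tailed p from the t distribution with n − 2
  degrees of freedom.
- **Degenerate inputs.** A constant response vector yields an explicit
  degenerate-fit result (r undefined) instead of an exception, so
  population runs do not abort on silent units.
- **Performance.** The (candidates × stimuli) unit-scale prediction
  matrix is built once per (grid, bank) and cached by the caller; each
  unit's fit is then a single mat-vec, so fitting hundreds of units with
  the full 65,536-candidate grid takes seconds.

Gradient-based (Gauss–Newton) fitting is deliberately out of scope: the
discrete grid evaluates the same candidate set for every unit, which is
what makes population comparisons fair.

## Sparsity screen

Kurtosis uses population (1/n) moments exactly as the statistic is
defined; the retention range [2.9, 42] is the range observed in V4
spiking data and is an overridable default. All-zero and constant units
are excluded with explicit reasons; a one-hot responder has K ≈ n − 2 and
is excluded by the upper bound.

## Translation invariance

TI is the ratio of summed off-diagonal covariances to summed SD products
across position columns. Implementation choices:

- Sample (n−1) covariance/SD estimators; the ratio is identical under
  population estimators (verified by an independent oracle in the tests),
  so the choice is cosmetic.
- Zero-variance columns inside the analysis window are dropped from both
  sums with a logged warning; treating them as zero covariance would bias
  TI toward 0 for sparse units.
- The reference position for the position-correlation profile is the
  window's center column. A constant non-reference column yields NaN
  (undefined), never 0.
- The RF profile is the per-position L2 aggregate √Σ responses², not the
  mean, because artificial responses may be negative.

The SVD separability index (first squared singular value over the sum of
squared singular values) is provided as the alternative metric; the test
suite includes a regression demonstrating its known bias — for spatially
confined response profiles with additive noise it stays ≈ 1 while TI
correctly collapses.

**CRF estimation.** The classical receptive field is measured by sweeping
the stimulus set across a 100-px span in 2-px steps (centers 64…164 of
the 227-px field); baseline is the response to the all-zero image, and a
position is responsive if any stimulus deviates from baseline by more
than a tolerance (default 0 for deterministic units; for trial data a
value of about twice the SEM is appropriate — the deviation tolerance is
deliberately a configuration option because no single value suits both).
CRF extent = (last − first responsive center) − maximum stimulus width
+ 1; by overlap geometry this estimator converges to about W − 1 for a
box RF of width W, within the 2-px sweep resolution. TI is computed only
over contiguous positions where the entire stimulus set fits inside the
CRF, and a unit must admit at least three 2-px translations to be
TI-eligible. Vertical sweeps reuse the same machinery transposed.

## Noise corrections

*Explained variance.* The correction assumes variance-equalized,
approximately normal per-stimulus means; the square-root transform is
applied before anything else (appropriate when variance grows linearly
with the mean, as for Poisson counts). The numerator subtracts a single
s̄²/n term exactly as the formula is printed; its validity here is
checked by simulation (200 Poisson units generated by a known model with
true R² = 1 at m = 362, n = 4 recover a mean corrected R² within 0.05 of
1) rather than re-derivation. Values outside [0, 1] are clipped and
flagged; the corrected r carries the sign of the raw regression slope.
The transform does not perfectly stabilize variance when many stimuli
have near-zero rates, which leaves a small conservative (downward)
residual bias visible in the simulation.

*TI noise ceiling.* TI is not a correlation coefficient, so its ceiling
is simulated: an ideal TI = 1 rate matrix is built by replicating the
best position's mean responses at the other positions, rescaled to match
each position's observed mean; Poisson trials are then drawn at the
original repeat counts (100 simulations by default) and the mean drop of
TI below 1 is an upper bound on noise-induced degradation. "Best
position" defaults to the greatest mean response across stimuli, with the
greatest single response exposed as an option. The corrected value
min(1, raw TI + drop) is an upper bound, not an unbiased estimate.

## Cross-validated model comparison

Each model family (APC grid; unit pool) selects its best candidate by
train-set correlation on a random 4/5 of stimuli and is scored by Pearson
r on the held-out 1/5, 50 times; the summary is the mean and the
[2.5, 97.5] percentile band of the test r distribution. Two families are
declared significantly different for a target when their bands do not
overlap — a deliberately conservative reading of "using the 95th
percentiles of the fit distribution", recorded here as an interpretation
since the exact construction (band overlap vs. a difference
distribution) is open. Splits are unstratified: rotations of one base
shape may appear on both sides, matching the original protocol's silence
on stratification. Pool candidates are scale-only least squares fits (no
intercept), matching the APC k convention, with an intercept available as
an option. When the pool equals the grid's own prediction vectors the two
procedures are algorithmically identical, which the tests assert exactly.

The residual ("orthogonalized") fit removes the APC-explained component
by least squares with an intercept — removing explained *variance*
requires the constant term — and then reports the best pool unit's
correlation with the residual; a near-zero-variance residual is flagged
rather than scored.

## Synthetic units

The generator produces the response classes the analyses consume, with
exact ground truth:

- **APC units**: forward-model responses; optional Gaussian noise or
  Poisson trials. Poisson rates are scaled so the best stimulus averages
  `rate_scale` counts per trial, default 50, keeping mean counts in the
  0–50 regime of cortical spiking data; tuning data use 3–5 repeats and
  invariance data up to 16, matching typical recording session sizes.
- **Positioned units**: values[s, x] = G(x)·((1−ε)T(s) + ε·T_x(s)) with
  G a positive Gaussian RF profile and T_x independent seeded
  permutations of T. Permuting (rather than redrawing) preserves the
  marginal response distribution at every position, so ε manipulates
  exactly the across-position correlation structure TI measures: ε = 0
  gives TI = 1 identically, ε = 1 gives TI ≈ 0, and TI decreases
  monotonically in between.
- **V4-like populations**: heterogeneous on-grid APC parameters,
  ε ~ U[0, 1], rate scales in 10–50, Poisson trials; every neuron ships
  its generating parameters for recovery scoring.

What the generator does *not* emulate: image-computable responses (units
here are descriptor-level; an image-domain unit is any callable from a
raster to a scalar, and the CRF sweep exercises that interface), firing
rate adaptation or serial dependence across trials, non-Poisson
dispersion, and correlated noise across stimuli or positions. Passing
tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to every property of real recordings.

## Network geometry

The architecture calculator propagates out = ⌊(in + 2·pad − kernel)/stride⌋ + 1
through a declarative sublayer list and accumulates receptive fields by
RF = 1 + Σ (kernel − 1)·(product of earlier strides). The bundled
AlexNet description counts 21 unit-bearing sublayers: the softmax output
is counted (it transforms values one-to-one per unit) while dropout
sublayers are not (they are the identity at test time and carry no
distinct units). Padding values (conv2 pad 2, conv3–5 pad 1, pools
pad 0) follow the Caffe AlexNet; grouped convolutions halve the kernel
depth where groups = 2. The resulting totals — 22,096 unique units,
10,568 biases, 60,954,656 weights, grids 55 → 6, receptive fields
11 → 163 px — are asserted exactly in the tests.

## Pipeline and reproducibility

`run_characterization` derives every random stream from the single config
seed via `numpy.random.SeedSequence` spawning, so reruns are
byte-identical. Each stage is callable standalone from its intermediate
tables. Problem sizes used by the shipped tests and benchmarks — the
362-stimulus bank, the full 16⁴ grid for recovery and shuffle runs,
100–200 seeded replicates for stochastic checks, reduced 4⁴–6⁴ grids for
pipeline-level smoke tests — were chosen as the smallest sizes at which
the statistics of interest are stable.

## Known limitations

- The shape bank is a parametric emulation with exact descriptors, not a
  reproduction of any historical stimulus set's pixel geometry.
- The correction formula's single-subtraction numerator is implemented as
  printed; a sensitivity analysis of the degrees-of-freedom factor is
  left to the simulation checks.
- `estimate_crf` evaluates the unit once per (stimulus, position), which
  is the honest black-box protocol but is the slowest path in the
  package for expensive unit callables.
- Rotation/scale invariance and alternative invariance or sparseness
  indices are out of scope.
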