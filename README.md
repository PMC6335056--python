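# artiphys

Characterize any stimulus→response unit — a model neuron, a network unit,
or a recorded cell — the way a V4 electrophysiologist would. The package
implements the full "artiphysiology" workflow for boundary-curvature
selectivity and translation invariance: a parametric closed-shape stimulus
bank, a response-sparsity screen, the angular-position-and-curvature (APC)
shape-tuning model with its grid fitter, a translation-invariance (TI)
statistic with receptive-field estimation, noise corrections for
trial-variable spiking data, and cross-validated comparison of competing
predictors. A synthetic-unit generator with exact ground truth makes every
stage testable without any trained network or neural recording, and a
network-geometry calculator reproduces the standard AlexNet architecture
accounting (unique units, parameters, grids, receptive fields).

## The models

**APC tuning.** The response of a unit to the *i*-th closed shape is the
maximum over the shape's boundary elements *j* of a product of two
Gaussian tuning curves, one in normalized curvature `c` (−1 sharp
concavity … +1 sharp convexity) and one in angular position `a` (degrees
about the shape's center, circularly wrapped):

    R_i = k · max_j exp(−(c_ij − μ_c)² / 2σ_c²) · exp(−(a_ij − μ_a)² / 2σ_a²)

Fitting enumerates a discrete grid — 16 linearly spaced means and 16
log-spaced SDs per dimension, 16⁴ = 65,536 candidates, endpoints
μ_c ∈ [−0.5, 1], σ_c ∈ [0.01, 0.98], μ_a ∈ [0°, 338°], σ_a ∈ [23°, 171°] —
selects the candidate maximizing the Pearson correlation between observed
and predicted responses (r is invariant to k), then sets k by least
squares.

**Translation invariance.** For a stimuli × positions response matrix
with mean-subtracted position columns `p_i`,

    TI = Σ_{i≠j} Cov(p_i, p_j) / Σ_{i≠j} SD(p_i) SD(p_j)

over unique position pairs. TI = 1 for exactly separable responses
(shape tuning × RF profile), ≈ 0 for uncorrelated columns, and is bounded
in [−1, 1]. The SVD separability index is included as the (biased)
alternative.

Supporting analyses: the kurtosis sparsity screen
`K = (1/n) Σ (x_i − x̄)⁴ / σ⁴` with retention range [2.9, 42]; CRF
estimation from a 100-px translation sweep (extent = longest responsive
run − maximum stimulus width + 1); the noise-corrected explained variance
`R²_c = (β̂² − s̄²/n) / (α̂² + β̂² − (s̄²/n)(m−1))` after a square-root
transform; and a simulated Poisson noise ceiling for TI.

## Worked example

```python
import artiphys as ap

bank = ap.generate_shape_bank(seed=0)          # 362 descriptor-level stimuli
grid = ap.build_grid()                          # 16^4 = 65,536 candidates

# a synthetic unit tuned to sharp convexities near 135 deg, Poisson trials
truth = ap.APCParams(mu_c=1.0, sigma_c=0.29, mu_a=135.0, sigma_a=45.0)
spec = ap.SyntheticUnitSpec(apc_params=truth, ti_mix=0.2,
                            noise=("poisson", 50, 5), seed=42)
responses, trials = ap.make_apc_unit(spec, bank)

K = ap.kurtosis(responses)
fit = ap.fit_apc(responses, bank, grid)
mat = ap.make_positioned_unit(spec, bank, positions=[-20, -10, 0, 10, 20])
ti = ap.ti_metric(mat)
print(f"kurtosis K = {K:.2f}")
p = fit.params
print(f"APC fit: mu_c={p.mu_c:.2f} sigma_c={p.sigma_c:.2f} "
      f"mu_a={p.mu_a:.0f} sigma_a={p.sigma_a:.0f}  r={fit.r:.2f} p={fit.p_value:.1e}")
print(f"TI = {ti:.2f}")
```

prints

```
kurtosis K = 3.52
APC fit: mu_c=1.00 sigma_c=0.29 mu_a=135 sigma_a=45  r=0.93 p=1.6e-162
TI = 0.94
```

K = 3.52 lies inside the [2.9, 42] retention range, so the unit passes the
sparsity screen. Despite 5-repeat Poisson noise the grid fit recovers the
generating parameters exactly (each is a grid candidate) with r = 0.93,
and the TI of 0.94 reflects the mild position-specific mixing
(`ti_mix=0.2`) the unit was built with.

A command-line interface wraps the same functions:

```sh
artiphys shapes --n-base 51 --seed 1 --out bank_dir
artiphys arch --report alexnet_report.csv
artiphys simulate --preset v4like --n 109 --seed 1 --out results_dir
```

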