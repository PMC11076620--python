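# Methods notes

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `grassmf`.

## Study design being modelled

Plot-level observational design for temperate agricultural grassland: plots
belong to farms; farms come in organic / non-organic pairs matched on
topography (the blocking factor); each plot carries three binary management
aspects — production system (organic vs. non-organic), eco-scheme extensive
management (yes/no; enrolled plots receive no fertilizer by policy), and
harvest type (pasture vs. meadow).  Twenty-two ecosystem-service indicators
map to 12 services in three categories (provisioning, supporting/regulating,
cultural).  Some indicators are disservices (smaller is better: nitrate
leaching, N₂O, heavy metals, soil compaction, pathogen load, weeds, leaf
damage) and some are log-transformed before Gaussian modelling.  The shipped
indicator/service map is a configurable default with field-typical names;
any mapping with the same column contract can be substituted.

## Level 1 — latent-variable multivariate regression

Model: `y_ij = x_i'β_j + u_pair(i) + λ_j'z_i + ε_ij` with `z_i ~ N(0, I_d)`
(d = 2 by default), `u ~ N(0, σ²_pair)` shared across indicators and plots
of a pair, `ε_ij ~ N(0, ψ_j)`.  The latent scores act as ordination axes:
they give the within-plot residual covariance the rank-2-plus-diagonal form
`ΛΛ' + diag(ψ)`, while the pair intercept adds a compound-symmetric
between-plot term.

Estimation is exact EM.  Because responses are Gaussian after preprocessing,
the E-step posterior of `(u, z)` per pair is available in closed form and the
marginal likelihood is exact — no variational approximation is needed; the
likelihood trace is recorded and checked non-decreasing.  Fits whose AICc and
estimates are compared against a variational implementation of the same model
will therefore differ slightly in the third digit.  Numerical choices:

* convergence when the relative log-likelihood change is below `tol`
  (default 1e-8) or after `max_iter` (default 2000) iterations;
  non-convergence is flagged on the fit, not raised;
* residual variances floored at 1e-10; a pair variance decaying to the
  boundary is truncated to exactly zero (mirrors random terms estimated as
  zero in blocked field data, and avoids an asymptotic EM crawl);
* loadings are reported in the lower-triangular, non-negative-diagonal
  rotation (the likelihood is rotation-invariant; the convention fixes a
  unique representative);
* the seed controls only the random jitter of the loading initialisation;
* standard errors are Wald SEs from the exact Fisher information of the
  coefficients at the converged variance parameters (per pair:
  `(X_g'X_g) ⊗ Σ_w⁻¹ − (σ²/c)(tt') ⊗ (ss')` with `s = Σ_w⁻¹1`,
  `t = Σ_i x_i`, `c = 1 + σ²n_g·1's`).

AICc uses `k` = coefficients + identified loadings (`pd − d(d−1)/2`) +
variances, and `n` = number of response cells (plots × indicators) by
default.  Counting plots instead (configurable) makes AICc undefined at the
86-plot study scale, where `k ≈ 154` exceeds the plot count; the cell
convention matches multivariate-regression practice.  Forward selection adds
the environmental covariate (pH, sand, elevation, inclination, northness;
SD-standardized) with the best AICc improvement until none improves, then
the three pairwise aspect interactions are screened as one block; AICc ties
retain the main-effects model.

## Level 2 — recursive path analysis

Per indicator, a standardized recursive system: inclination → eco-scheme and
harvest type (production system receives no topography path — matching
removes that dependence by construction); each aspect → each intensity
variable (fertilizer N, cuts, grazing LU-days); aspects + intensities →
indicator.  Binary aspects enter as standardized 0/1 dummies
(linear-probability treatment, the default behaviour of covariance-based
path modelling).  Equation-wise least squares is the ML solution for a
recursive system; residual covariances among the three intensity variables,
between the two topography-driven aspects, and between production system and
those aspects are left free and estimated from residual cross-moments.

Indirect effect via mediator M = path(aspect→M) × path(M→indicator); total =
direct + Σ indirect.  For this linear recursive structure the total equals
the aspect's coefficient in the reduced-form regression of the indicator on
the aspects — an exact in-sample identity used as a correctness check.  A
mediated component is flagged significant only when both constituent paths
are (joint-significance rule, matching the binary significant/insignificant
rendering of path diagrams); Sobel-type alternatives were considered and
left out of the default because the joint rule is the more conservative and
the more common rendering.  Fit statistics: `χ² = (n−1)·F_ML` against the
sample covariance, CFI against the independence baseline, SRMR on
standardized residual covariances.  A saturated model (every variable on all
predecessors) reproduces the sample covariance exactly (χ² = 0, df = 0).

## Level 3 — MLRR multifunctionality

For a contrast, `LRR_j = ln(mean_treated/mean_reference)` on the *raw*
indicator values, multiplied by −1 for disservices.  Group means are
marginal over the other aspects (whole treatment levels are compared).
Common positive per-indicator scalings cancel in the ratio, so the MLRR is
identical on raw and max-scaled data — tested exactly.  Indicator LRRs are
averaged per service, services averaged to the MLRR (overall or per
category), which equals a grand mean weighting each indicator by one over
its service's indicator count.  `e^MLRR` is the effect on the linear scale.

Zero handling: if a group contains zeros, half the smallest positive
observed value of that indicator is added to both group means before the
ratio (logged, configurable); a non-positive mean after the guard raises.

Bootstrap CIs are percentile intervals.  The default resampling unit is the
**farm pair** (block bootstrap over the design's exchangeable sampling
units): plot-level stratified resampling is also provided but ignores the
within-pair correlation induced by the pair random effect and, in
calibration runs under the null (all multipliers 1, n = 400, B = 1000), was
found to underestimate the MLRR standard error by roughly 20% (≈ 86–90%
coverage of a nominal 95% interval), while the pair-block scheme covers at
≈ 95%.  B defaults to 10,000.

Comparison metrics: the per-plot averaging index (row mean of the
preprocessed matrix; loses information because opposite deviations cancel)
and a model-estimate index (regression coefficients aggregated through the
same service weighting).  On synthetic data both rank the aspects like the
MLRR.

## Synthetic-data generator

The generator is first-class, tested code defining the conditions under
which every downstream claim is verified.

* **Design**: pair-level topography/soil (elevation uniform on 435–1145 m,
  inclination gamma with mean 12°, northness uniform on [−1, 1], pH and sand
  normal) with small within-pair jitter, so pairs are matched; per-cell plot
  counts over the 2×2×2 aspect combinations default to an 86-plot allocation
  (11/11/10/11 per production system) and are configurable.  Eco-scheme and
  pasture assignment respect exact cell counts while being tilted toward
  steeper plots (Gumbel-top-k weighted sampling; slope 1.2 per SD of
  inclination, zero slope recovers uniform assignment).
* **Management intensity**: gamma-distributed with the group means and SDs
  of mid-intensive Central European grassland — available fertilizer N
  46.3 ± 52.4 (organic pasture), 82.6 ± 42.8 (organic meadow), 75.7 ± 55.8 /
  111.6 ± 55.7 (non-organic) kg N ha⁻¹ yr⁻¹ on non-eco-scheme plots, zero
  on eco-scheme plots by policy; meadows ~4.5 cuts yr⁻¹ vs. pastures ~1.2;
  grazing ~160 LU-days ha⁻¹ yr⁻¹ on pastures vs. ~15 on meadows, with the
  eco-scheme reducing cutting and grazing intensity.  This reproduces the
  field-typical correlation pattern (mowing ↑ with fertilization, mowing ↓
  with grazing).
* **Indicators**: log-linear model `log y = log b_j + Σ active log m_ja +
  u_pair + λ_j'z + ε`, so effects are multiplicative and the true signed
  LRR is exactly `±log m_ja`.  Default multipliers emulate the qualitative
  pattern reported for such systems: eco-scheme boosts cultural and most
  regulating indicators (×1.3–1.7) at the cost of provisioning (×0.5–0.8)
  and of a few intensity-loving indicators (earthworms, weed control, N₂
  fixation); pasture boosts cultural indicators with livestock presence
  dominating (×4); organic production affects only AM fungi (×1.25) and
  nitrate leaching (×0.85).  `pair_sd = 0.15`, per-indicator residual log-SDs
  0.10–0.35, and a fixed rank-2 loading pattern (productivity axis +
  soil-biology axis) were chosen once as field-plausible magnitudes.

What the generator does *not* emulate: environmental effects on indicators
(off by default, so env forward selection faces pure noise; plantable via
`env_effects` for power checks), mediation of treatment effects through the
intensity variables (indicators respond to aspects directly; mediation
recovery is exercised through the linear recursive simulator in
`path_effects`), non-Gaussian measurement error, spatial autocorrelation,
and temporal dynamics.  Passing tests therefore demonstrate correctness of
the estimators under the stated generative assumptions, not robustness to
real-data pathologies.

## Derived indicators

All literature coefficients (organic-N availability fractions, emission and
leaching factors, the packing-density clay coefficient, heavy-metal
references, N-fixation parameters) live in a versioned YAML config with
provisional defaults labelled as such; the code contains no study-specific
constants.  N₂O is reported as N₂O-N with an optional ×44/28 mass
conversion.  Directly measured indicators are pass-through columns validated
for finiteness and non-negativity.

## Preprocessing

Default order: log transform (flagged indicators; offset of half the
smallest positive value when zeros are present) → max-scale (column maxima
1) → disservice reversal.  Reversal is implemented as `max − value`, which
keeps values non-negative and flips only the sign of effects relative to
reflecting below zero; it is not an involution (applying it twice yields
`value − min`).  The transform order is config-visible for sensitivity
checks.  The whole chain is a deterministic pure function of matrix,
metadata, and config.

## Problem sizes used in the test suite

Exact invariances run at the 86-plot study scale.  Parameter-recovery checks
use n = 2000 plots with 200 replicates (bias) and B = 2000 bootstrap
replicates (coverage); null calibration uses 500 replicates at n = 400,
B = 1000; model-selection and interaction-screen simulations use 8–20
replicates at n = 120–200 with 5–6 indicators.  These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances while keeping the
default suite in the minutes range on one CPU.

## Known limitations

* The farm-pair intercept is shared across indicators with a single
  variance; per-indicator pair effects would add 21 variance parameters and
  are out of scope.
* Only Gaussian responses; indicators must be transformable to approximate
  normality.
* The path models are fully observed and recursive (no latent SEM, no
  feedback loops); binary endogenous aspects are treated linearly.
* Percentile bootstrap intervals; BCa or studentized intervals are not
  implemented.
* The AICc observation count for multivariate responses is a convention
  (cells vs. plots); both are offered, results at small n depend on the
  choice.
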