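# Methods

## Scope and data model

The package reimplements the computational analysis of a batch adsorption
study (diazinon on acid-treated pumice) as a reusable library plus numbered
analysis drivers. The raw measurements of the original study are not
distributed; only its fitted artifacts are public (the quadratic
response-surface coefficients, and the linear/nonlinear parameter tables for
six isotherms and four rate laws). Those published values are shipped as
reference fixtures (`PUBLISHED_QUADRATIC`, `REFERENCE_ISOTHERMS_NL`,
`REFERENCE_KINETICS_NL`) and double as ground truths for the synthetic-data
generators, so every stage of the pipeline can be exercised and checked
end to end.

## Response-surface model

The removal efficiency (%) is modelled as the full second-order polynomial
in pH (X1), contact time (X2, min), initial concentration (X3, mg/L) and
adsorbent dosage (X4, g/L):

    y = b0 + Σ bi Xi + Σ bij Xi Xj + Σ bii Xi²   (15 coefficients)

- **Design.** Rotatable central composite design: 2⁴ factorial, 8 axial
  points at α = (2⁴)^¼ = 2, six center replicates → 30 runs. The study's
  exact five-level table is not public; the defaults used here are pH 7 ± 2
  (range 3–11), time 20 ± 5 min (10–30), concentration 6 ± 2 mg/L (2–10),
  dosage 2.2 ± 0.9 g/L (0.4–4), chosen so the coded box reproduces the
  reported optimum region; all are configurable through `FactorSpace`.
  Under this assignment the published quadratic evaluated at its reported
  optimum gives ≈75–77 % removal; no other factor-to-symbol assignment does.
- **Fit.** Ordinary least squares on the 15-column expansion. A rank check
  names collinear columns before failing.
- **ANOVA.** Partial (Type-III) sums of squares by single-column deletion,
  F = MS_term/MS_residual; sequential (Type-I) SS available by flag. Pure
  error comes from the center replicates; lack-of-fit is the remainder of
  the residual SS. Without replicates the lack-of-fit rows are omitted with
  a warning.
- **Pareto shares.** P_i = 100·b_i²/Σb_j² over all 14 non-intercept
  coefficients by default (a linear-terms-only variant is exposed). On the
  published coefficients the concentration linear term carries ≈73 % of the
  squared-coefficient mass. Note these shares are computed on actual-unit
  coefficients and are therefore unit-dependent; computed on coded
  coefficients the ranking can differ, which is why no exact share value is
  treated as a reproduction target.
- **Optimization.** The box-constrained maximum of a quadratic is found
  exactly: every face of the box (each factor at a bound or interior,
  3⁴ = 81 cases) contributes the solution of its restricted stationary
  system, and the best feasible candidate wins. Unbounded requests are
  refused unless the relevant Hessian block is definite.

## ANN–GA surrogate

A single-hidden-layer feed-forward network (4 inputs, tanh hidden units,
linear output) with inputs and response min–max scaled to [−1, 1]:

- **Training.** Levenberg–Marquardt on the training-set SSE with an analytic
  Jacobian; damping starts at 1e−3, ×10 on a rejected step, ÷10 on
  acceptance. Rows are split 70/15/15 (train/validation/test, rounding
  toward train) by a seeded permutation. Training stops after `epochs_max`
  (default 1000 available, drivers use 300), when damping is exhausted, or
  after 6 consecutive epoch-over-epoch validation-MSE increases; the weights
  at the best validation MSE are returned. Initialization is
  Nguyen–Widrow-style, seeded.
- **Width selection.** Candidates 1–14 hidden neurons, identical seed/split
  per candidate, argmin validation MSE with ties (within 1e−8) broken to the
  smaller width.
- **GA.** Real-coded: tournament selection (size 3), per-gene blend
  crossover, Gaussian mutation (sd 0.1 of the gene range) clipped to bounds,
  elitism of 2; the best individual ever evaluated is returned. Its role is
  maximizing the trained surrogate over the process box; an optional
  GA-seeded *weight* initialization (`train_lm(..., ga_init=True)`) covers
  the alternative reading in which the GA tunes weights, but process-space
  optimization is the default because the reported outputs are optimal
  process conditions.
- **Sample-size caveat.** A 30-point design cannot pin down the 49 weights
  of an 8-neuron net. With best-validation-weight semantics and a 4-point
  validation set, the returned net's training R² on 30-point data varies
  widely across split seeds; a training R² near 1 at this sample size is a
  lucky-split outcome, not a reproducible property. The surrogate's
  accuracy claims in the tests are therefore made on a 400-point noiseless
  sample of the quadratic surface, where training R² > 0.99 and a GA optimum
  within 1 % of the exact quadratic maximum are robust.

## Isotherm and kinetic library

Standard textbook forms, fixed to be consistent with the published units
(the source tables print parameters and units but not the expressions):

| model | qe(ce) or qt(t) | parameters |
|---|---|---|
| Freundlich | K_F·ce^b_F | K_F, b_F |
| Langmuir | K_L·b_L·ce/(1+b_L·ce) | K_L (mg/g), b_L (L/mg) |
| Temkin | B_T·ln(K_T·ce) | B_T, K_T |
| Redlich–Peterson | K_R·ce/(1+a_R·ce^α) | K_R, a_R, α |
| Sips | K_s·b_s·ce^n/(1+b_s·ce^n) | K_s, b_s, n_s |
| Toth | K_th·ce/(b_th+ce^n)^(1/n) | K_th, b_th, n_th |
| PFO | qe(1−e^(−K1 t)) | K1, qe |
| PSO | K2 qe² t/(1+K2 qe t) | K2, qe |
| Weber–Morris | K_id √t | K_id (no intercept; optional C off by default) |
| Boyd | qe(1−(6/π²)e^(−Bt)) | B, qe |

The Boyd form is the single-exponential film-diffusion truncation, so its
parameter pair matches the published table; its qt(0) = qe(1−6/π²) ≠ 0 is an
artifact of that truncation. Limiting-case identities (Sips n=1 and R–P α=1
collapse to Langmuir; Toth n=1 is Langmuir-shaped with plateau K_th) are
asserted in tests.

**Linearizations.** Freundlich: ln qe on ln ce; Langmuir: ce/qe on ce;
Temkin: qe on ln ce; PFO: ln(qe_exp−qt) on t (requires qe_exp > max qt, rows
at/above the ceiling dropped with a warning); PSO: t/qt on t; Weber–Morris:
qt on √t through the origin; Boyd: Bt = −0.4977−ln(1−qt/qe_exp) on t through
the origin. The three-parameter isotherms admit no exact linearization: the
exponent is scanned on a 0.005 grid over (0.05, 2], each candidate solved by
its conditional straight line, the original-scale SSE decides, and the
result is flagged approximate.

## Nonlinear fitting and metrics

`de_fit` minimizes original-scale SSE by differential evolution
(rand/1/bin; population 15 per dimension, F = 0.7, CR = 0.9, up to 2000
iterations, convergence tolerance 1e−10, L-BFGS-B polish), with parameter
bounds (1e−6, 1e3) and exponents in (0.05, 2] unless a model declares
tighter. Two numerical choices matter for robustness and were adopted after
observing population stagnation on rate-law saturation plateaus (large K1
makes qt ≡ qe for every sampled t, a flat region covering most of a
uniformly sampled box):

1. the initial population is sampled **log-uniformly** (all fitted
   parameters are strictly positive scale/rate constants), and
2. **three independent DE runs** with seeds derived from the user seed are
   performed and the lowest-SSE result kept.

Everything stays deterministic given the seed. The objective is SSE rather
than RMSE (monotone-equivalent, cheaper).

The metric suite reports R² = 1 − SSE/Σ(obs−mean)², RMSE = √(SSE/(n−1)),
SAE = Σ|e|, SSE = Σe², ARE = (100/n)Σ|e|/obs, all on the original scale for
both fitting routes. Two flags preserve the source report's literal
formulas for audit: `r2_as_printed` computes the error-over-spread ratio the
source prints as Eq.-style "R²" (which would be near 0, not 1, for good
fits — treated as a typographical slip), and `are_divisor="p"` divides ARE
by the parameter count instead of n. ARE is reported as missing when any
observation is zero.

## Thermodynamics

Ke° = b_L·(M·1000 mg/mol)·(1 mol/L)/γ converts the Langmuir **affinity**
constant (L/mg) to a dimensionless equilibrium constant; the monolayer
capacity (mg/g) has no concentration-inverse units and is never used for
this, despite looser wording in parts of the literature. M defaults to
diazinon's 304.35 g/mol and γ to 1 (dilute solutions), both configurable.
ΔG°(T) = −RT ln Ke° (kJ/mol, R = 8.314 J/(mol·K)); van't Hoff regression of
ln Ke° on 1/T gives ΔH° = −R·slope and ΔS° = R·intercept. A
temperature-independent series is handled as a perfect constant fit rather
than an undefined correlation. The temperature list defaults to
293/303/313/323 K (20–50 °C in 10 °C steps).

## Synthetic data

Generators are pure functions of (ground truth, grid, noise sd, seed):

- `gen_ccd_response` — CCD table + quadratic truth + N(0, sd²), clipped to
  [0, 100] %; default sd 0.5 % reflects the stated replicate variability of
  under 2 % of the response. Clipping events are counted and returned so
  tests can require zero truncations.
- `gen_equilibrium` / `gen_kinetics` — 21 points on ce = 0.5–50 mg/L and
  t = 3–30 min by default, additive Gaussian noise truncated at 0.
- `gen_thermo_series` — Ke(T) from a chosen (ΔH°, ΔS°), back-converted to
  b_L, so the van't Hoff fit round-trips exactly.

What they emulate: smooth responses with homoscedastic additive noise at
the study's stated variability. What they do not emulate: instrument drift,
heteroscedastic concentration-dependent error, pH-dependent speciation, or
adsorbent heterogeneity. Passing round-trip tests therefore demonstrates
correctness of the estimators under the assumed error model, not the field
behavior of the adsorbent.

## Problem sizes used in tests and drivers

Analysis drivers and tests run the 30-run design, 21-point isotherms,
10-point kinetics, 4-temperature series; DE fits use the default
hyperparameters (noisy-replicate suites cap iterations at 300 with
tolerance 1e−8); the ANN accuracy suite uses 400 noiseless surface points
and LM capped at 300 epochs; GA budgets are 80 individuals × 200
generations. These sizes were chosen as the smallest at which every
asserted property is stable across seeds.

## Known limitations

- The quadratic optimizer is exact only for quadratics; it is not a general
  NLP solver.
- Three-parameter isotherm "linear" fits are grid-conditional
  approximations by construction.
- The equilibrium capacity of rate laws (qe of PSO in particular) is weakly
  identified from a 3–30 min trace that ends far from equilibrium; under
  noise its estimate carries several-percent spread even when the curve fit
  is excellent.
- The ANN surrogate is honest only inside the fitted scaling box;
  extrapolation warns rather than fails.
- Published linear-column parameter sets are not reproduction targets: they
  depend on the original raw data, which is not distributed.
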