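# Methods

This note records the modelling choices behind `prognosim`: what each
component assumes, which parameters matter, what the synthetic data does
and does not emulate, and where the design was genuinely open.

## Synthetic cohorts

The generator (`prognosim.synthetic`) emulates a breast-cancer registry
table. No public parameterization exists for these marginals, so they
are the package's own choices, fixed once to resemble published
summaries of large breast-cancer cohorts:

| column | distribution | default shape |
| --- | --- | --- |
| ageatdiagnosis (years) | 25 + Gamma(6, 6) | mean ≈ 61, right-skewed |
| tumor_size (mm) | LogNormal(3.1, 0.55) | median ≈ 22, right-skewed |
| tumor_stage | categorical 1–4 | (.22, .48, .25, .05) |
| neoplasm_histologic_grade | categorical 1–3 | (.12, .42, .46) |
| lymph_nodes_examined_positive | NegBinom(0.9, 0.31) | mean ≈ 2, zero-inflated |
| mutation_count | Poisson(exp(log 5.5 + 0.35·z)) | mean ≈ 5.5, latent-linked |
| expression E_g | exp(1 + 0.8·z·[g even] + 0.4·ε) | log-normal, latent-linked |

Survival is exponential proportional-hazards: per-patient hazard
λᵢ = λ₀·exp(Σ w_f·z_f,i) on within-cohort z-scored features, with
λ₀ = ln 2 / 120 months (median survival 10 years at covariate means) and
default per-SD log-hazard weights 0.40 (mutation count), 0.30 (nodes),
0.25 (size), 0.30 (grade), 0.15 (age). Censoring: each patient is
independently censored with probability `censor_rate` (default 0.3), in
which case follow-up ends at a Uniform(0, T) fraction of the true event
time — the marginal censoring fraction is exact while the mechanism
stays an independent uniform follow-up. A small fraction (5%) of deaths
are from other causes, exercising the cleaning rule. Missingness is
injected completely at random, matching the assumption behind
mode/mean imputation.

A shared standard-normal latent factor z drives both mutation count and
the even-indexed expression columns, so low-rank compression has genuine
structure to find and expression carries survival signal through the
mutation-count hazard.

**What passing tests do not show about real data:** the generator has no
batch effects, no informative censoring, no non-proportional hazards, no
measurement error in the clinical covariates and a single latent
expression factor. Performance on it bounds implementation correctness,
not clinical accuracy.

Trajectories (`generate_trajectory`) are exact solutions of
dN/dt = r·N(1 − N/K) − d·N sampled at unit times with additive Gaussian
observation noise; noise is observational and is therefore not clamped
at zero.

## Expression kinetics

Probe-binding, transcript and field dynamics are linear ODEs and are
solved in closed form; the near-degenerate transcript eigenvalue
(k_t − k_dr ≈ −k_dm) is evaluated through `expm1` so accuracy is uniform
across the parameter space rather than branching on an equality test.
Only the spatial field, whose creation rate may be an arbitrary function
of time, is stepped with explicit Euler (stable for dt below the
inverse degradation rate). The displayed transcript equation
dR/dt = (k_t − k_dr)R is implemented as written; a `sign_flip` flag
provides the opposite sign convention that appears in some verbal
descriptions of the same system, and is off by default.

## Agent-based simulator

Updates are synchronous from previous-step values, which removes
agent-ordering artifacts. Per-step order: nutrient diffusion → size and
expression updates → division/death → immune phase → consumption and
replenishment.

Defaults (all the package's own choices — sizes, nutrient and time are
left unitless):

* grid 21×21, fixed non-periodic edges (tumors are bounded);
* growth r = 0.25/step, K = 200 cells, d = 0.02/step, dt = 1;
* size update ΔS = r·(1 + 0.5·E_growth)·ν·(1 − N/K) − d with
  ν = nutrient/(nutrient + 0.5), a Michaelis–Menten limitation;
* division when S ≥ 2·S₀, daughter on a uniformly chosen free 4-neighbor
  with halved size; blocked when no neighbor is free or N ≥ K (this cap
  is what bounds N by K + 1 under logistic dynamics);
* death when S ≤ 0;
* expression dynamics in two modes: `logistic`
  (dE = Signals·E·(1 − E/h), h a capacity) and `additive`
  (dE = g − h ± k·A, h a flat turnover), because both readings of the
  update law describe defensible biology; levels clamp at 0;
* nutrient: 4-neighbor zero-flux Laplacian mixing (fraction
  `diffusion_coeff` = 0.2), flat consumption 0.01 per occupied site, and
  relaxation toward the initial level at rate 0.05 — the replenishment
  constant stands in for vascular supply, the only role endothelium
  plays here;
* immune agents move one lattice step toward the nearest cancer cell
  (Manhattan metric, random tie-breaks), activate on adjacency, and
  remove `kill_rate` size units from the adjacent target per step.

Relapse applies to the **total** tumor size series (the threshold is a
tumor-burden criterion, not a single-cell one), inclusive of equality.
Overall survival is the time of the relapse endpoint capped at T_max·dt,
and T_max is returned when nothing fires. S_threshold = 300 with
T_max = 150 places baseline relapse mid-run, leaving headroom to observe
both earlier relapse (higher r) and later relapse (knockouts, higher d).

Virtual knockouts force one gene's expression to zero for the entire run
(initial value and after every update) and rerun under the same seed, so
divergence is attributable to the silenced gene. Replicate experiments
treat never-relapsing runs as relapsing at the horizon, a conservative
right-censoring convention.

Calibration fits (log r, log K) of the deterministic closed-form curve
to observations by SSE, holding d at its initial value: Nelder–Mead with
three deterministic restarts (xatol 1e-10), or an affine-invariant MCMC
ensemble (16 walkers, 600 steps, 250 burn-in, Gaussian error with σ set
to 1% of the trajectory maximum, log-uniform prior box of ±8 natural-log
units). Posterior medians are reported.

## Preprocessing

* Cleaning removes deaths from causes other than the cancer (their
  follow-up time is uninformative for disease-specific prognosis) and
  demotes `patient_id` to a row key. Idempotent.
* Imputation: mode for non-numeric columns, mean for numeric ones; a
  fully missing column is an error rather than a silent constant.
* Collinearity pruning is greedy in column order at |r| > 0.6, with the
  Nottingham composite (0.2·size(cm) + nodal stage + grade) visited
  first so the composite survives and its components drop. Greediness
  plus a fixed order makes the retained set deterministic.
* Log transform is the natural log (fixed for determinism), renaming to
  `log_age` / `log_tumor_size`; nonpositive values are an error.
* Horizon labels: y = 1 iff died of disease within 12·t months; y = 0
  iff follow-up exceeds the horizon; censored at or before it ⇒
  excluded, since calling an unobserved patient a survivor would bias
  the classifier optimistic. Equality (censored at exactly 12·t months)
  excludes. Years convert at exactly 12 months. All eight horizons
  t = 2..9 are fitted.

## Survival model

* Features are standardized before SVD — mm, counts and years on raw
  scales would let unit variance, not structure, pick the vectors.
* m is the smallest count of singular vectors reaching the cumulative
  explained-variance target (default 0.90), never exceeding numerical
  rank.
* Logistic fits use liblinear, L2 penalty, 1000 iterations, C = 1, and
  stratified k-fold CV (default 20 folds, capped at the minority-class
  count) with mean AUC-ROC as the accuracy metric — the outcome classes
  are imbalanced, which is also why folds are stratified. Fold shuffling
  is seeded; identical seeds reproduce coefficients exactly.
* The pipeline fits **one** SVD basis on the full cleaned matrix and
  shares it across horizons. θ(t) is defined under ∂ω/∂t = 0; per-horizon
  bases would break the comparability of β(t) across t, so the shared
  basis is a structural requirement of the derivative, not an
  optimization.
* ∂β/∂t uses centered finite differences at interior horizons and
  one-sided at the ends.
* Extrapolation modes: `taylor` (default) applies the logistic chain
  rule ∂f/∂t = f(1−f)·θ, which is second-order accurate in Δt for a
  logit drifting linearly in t; `paper` uses the variant slope (f−1)·θ,
  equivalently f·(θΔt+1) − θΔt, retained for fidelity to the derivation
  it originates from. Outputs clamp to [0, 1].
* Probabilities are oriented as **survival** (probability of living
  beyond t) wherever they are reported; the classifier's class-1
  probability is the death probability and is converted at the surface.
* Gamma curves fit p ≈ a·(1 − GammaCDF(x; k, θ)) + c by least squares
  with shape/scale in log space (positivity by construction) and five
  deterministic multi-starts over a shape/scale grid. The decreasing
  survival-vs-count pattern motivates the 1 − CDF form. When the
  observed range covers only the near-linear part of the CDF the four
  parameters are weakly identified — amplitude and offset can trade off
  against large scales — but the fitted curve itself is stable and
  monotone, which is what downstream checks consume.

## Evaluation

* The concordance index is the standard concordant-pair fraction with
  Harrell comparability under censoring (the shorter time must be an
  event), prediction ties counting ½ and time ties skipped. The printed
  formula this statistic usually travels under is typographically
  garbled in places; the implementation follows the behavioral anchors
  that define it — exactly 1 for perfect ranking agreement, 0.5 in
  expectation for random predictions — and is cross-checked against an
  independent brute-force pair enumeration and `scikit-survival`.
* ROC curves sweep every observed score as a threshold (calls are
  score ≥ threshold); AUC is trapezoidal and equals positive-negative
  pair concordance, which the tests verify against `scikit-learn`.
* Calibration uses equal-width bins on [0, 1], omitting empty bins.
* A percentile-bootstrap CI helper (95%, seeded) is provided; resamples
  that degenerate (single class, no comparable pairs) are skipped.

## Pipeline determinism and sizes

A single top-level seed fans out to per-stage child seeds by fixed
offsets (cohort, CV folds, permutation null, per-patient simulations),
so stages are independently reproducible and the full report is
byte-identical across reruns. The manifest records the seed, a hash of
the analytic configuration (output location excluded), and record counts
after each filter.

Default experiment sizes — 2000-patient cohorts for signal-detection
checks, 20 paired replicates for simulator monotonicity claims, 500
replicates for the random-concordance anchor — were chosen as the
smallest sizes at which the Monte-Carlo noise of each quantity is an
order of magnitude below the effect being asserted.

## Known limitations

* The simulator is 2-D, single-lattice, with one cell per site; no
  vascular growth, pharmacokinetics or 3-D geometry.
* The survival generator's exponential baseline cannot express
  late-crossing hazards; the statistical arm has only been demonstrated
  against proportional-hazards truth.
* Gamma-curve parameters are weakly identified on short feature ranges
  (see above); interpret the curve, not the raw (k, θ, a, c).
* `overall_survival` recognizes a single endpoint (relapse); treatment
  "death events" enter only through their effect on that endpoint.
* The CLI `predict`/`extrapolate` commands re-standardize features on
  the scoring cohort; scoring a cohort distributed very differently from
  the training cohort shifts the operating point.
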