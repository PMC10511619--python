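# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the shipped tests do and do not demonstrate.

## The modelling problem

Each subject contributes a vector of plasma lipid peak intensities (plus,
optionally, clinical covariates) and an ordinal disease label: 0 for
cancer-free controls, rising codes for increasing severity (cancer, liver
metastasis; or tumour stages I–IV). The working assumption behind the ordinal
coding is that informative biomarkers rise or fall monotonically with disease
severity, so a *regression* onto the codes — rather than a nominal
classifier — is the natural model, with continuous predictions rounded back
to the nearest code for evaluation.

## Sparse MLR-EM

The feature-selection model is linear regression with a Laplacian
(double-exponential) prior on the standardized coefficients. The EM treatment
of that prior replaces it at each iteration by its local quadratic bound,
making the M-step a reweighted ridge solve:

    (XᵀX/n + β·D(t)) w(t+1) = Xᵀy/n,   D(t) = diag(1 / max(|wᵢ(t)|, ε)).

Fixed points with nonzero weights satisfy the lasso stationarity condition
`Xᵀ(y − Xw)/n = β·sign(w)`; the test suite cross-checks converged solutions
against an independent coordinate-descent lasso solver. The iteration also
gives the method its characteristic behavior: weights driven toward zero are
re-penalized ever harder, collapse below the pruning threshold, and leave the
active set, so the surviving-panel size decreases as β grows.

Numerical choices:

- columns z-scored, response centred; coefficients reported on the
  standardized scale with a raw-scale back-transform;
- `ε = 1e−9` guards the reweighting; `prune_tol = 1e−6` (standardized scale);
  convergence when the largest weight change falls below `1e−8`, capped at
  500 iterations;
- initialization is the ridge solution with penalty β·I — symmetric and
  deterministic, so duplicated columns keep identical weights and the fitter
  has no random state;
- β = 0 short-circuits to least squares on the full active set (the OLS
  limit used as an oracle in the tests);
- the normal equations are divided by n so that β is comparable across
  cohort sizes; on unit-spaced ordinal codes the informative sweep range is
  roughly 0.05–0.6, and the default sweep grid (0.05, 0.08, 0.12, 0.2, 0.35,
  0.6) spans panels from dozens of features down to none. The numeric scale
  of β is specific to this formulation; only its qualitative role (larger β,
  smaller panel) transfers across implementations.

Panel selection over the sweep takes the smallest β whose panel size falls in
an advisory window of 9–12 features — the panel size needed for statistically
stable discrimination at these cohort sizes — falling back to the best
size-penalized training r² when no β lands in the window.

Per-coefficient t-statistics and p-values come from an unpenalized
least-squares refit on the selected panel (residual-variance SEs, Student t
with n − k − 1 degrees of freedom). They are *nominal*: no adjustment is made
for the preceding selection step, and they should be read as descriptive
ranking scores, not calibrated inference.

## Bayesian-regularized neural network

The nonlinear comparator is a single-hidden-layer network (default 3 tanh
units, linear output) trained by damped Gauss–Newton (Levenberg–Marquardt)
on the regularized objective

    F(w) = β_noise·E_D + α·E_W,   E_D = Σ(y − ŷ)²,  E_W = ½Σw²,

with MacKay-style evidence re-estimation between descent phases:
γ = N_w − α·tr(H⁻¹) (effective parameters), α = γ/(2E_W),
β_noise = (n − γ)/(2E_D), H ≈ 2β_noise·JᵀJ + αI. Regularization replaces
early stopping; γ reports how many of the N_w weights the data determine and
is exposed as a diagnostic.

Numerical choices: inputs z-scored and the target standardized; weights
initialized from the seeded stream at scale 1/√fan-in (training is
deterministic given the seed); convergence on hyperparameter stability
(relative shift < 1e−8) with a 200-outer-iteration cap; β_noise capped at
1e9 so that interpolating fits (E_D → 0, common when the selected panel
nearly spans the training responses) stay numerically stable, with the
clamp recorded on the model; a constant target short-circuits to the zero
network (predicts the mean, γ = 0).

With ~10-feature panels and ~50 samples this architecture has more weights
than samples; the evidence updates are what keep it from overfitting freely,
and on monotone (near-linear) class structure it should — and in the tests
does — perform on par with the linear model rather than beat it.

## Evaluation conventions

- **Stratified split**: per-class test count `round(0.2·n_class)` (half
  rounds up), minimum one test sample per class, sampled without replacement
  from a seeded generator.
- **Rounding**: continuous predictions map to the nearest class code; exact
  midpoints map to the lower code; out-of-range predictions clip to the
  extremes. With three classes this bounds any error at two stages, so
  tolerance-2 accuracy is identically 1 — tolerance accuracies are only
  informative up to the code span minus one.
- **"Standard error"** is defined here as the RMSE of the continuous
  predictions, √(Σ(y−ŷ)²/n) — on unit-spaced codes this is the natural
  companion to the accuracies. **r²** is the squared Pearson correlation
  between truth and prediction; the variance-explained form (1 − SSE/SST) is
  also computed and exported, but the correlation form is canonical here. A
  constant prediction vector has undefined correlation and is reported as
  r² = 0 with a flag.

## Survival analysis

Kaplan–Meier product-limit estimation with the events-before-censorings tie
convention and Greenwood variance; the k-sample log-rank test uses the
hypergeometric covariance over shared risk sets with k − 1 degrees of
freedom. Endpoint horizons — 60 months for disease-free survival, 96 months
for overall survival — are applied as administrative censoring; an at-risk
table is reported at 12-month ticks. The estimator and test are verified
exactly against a brute-force risk-set loop and against lifelines.

## Synthetic cohorts

The generator emulates the statistical structure of a plasma-lipidomics
case/control study; its defaults define the study conditions used throughout
the tests and the acceptance script.

- **Intensities** are log-normal (positive, right-skewed, as LC-MS peak
  intensities are): baseline log-mean 13 (≈ 4.4×10⁵ raw, order unity after
  the 1/100,000 scaling), shape σ = 0.5 (≈ 50% CV, mid-range for plasma
  lipid profiling).
- **Planted biomarkers**: a small panel (9 of 333 features in the three-group
  preset) shifts its log-mean by `effect_size × class_code × direction`,
  direction ±1 fixed per feature — monotone in severity by construction.
  `effect_size = 1.0` per unit code for the 0/1/2 and 0/1 presets; 0.5 per
  stage for the 0–4 preset so the total span stays comparable.
- **Technical replicates**: the presets generate 3 replicates per biological
  sample (replicate noise σ = 0.1 on the log scale) because the outlier-
  elimination rule — leave-one-out z-score over replicates, threshold 3 SD —
  operates on replicates; without them sporadic spike artifacts cannot be
  removed and measurably degrade panel recovery.
- **Artifacts**: 1% of replicate-level cells become 10× multiplicative
  outliers (detector spikes); 5% become missing completely at random.
  Real LC-MS missingness is partly intensity-dependent (censoring at the
  detection limit); that mechanism is *not* emulated, so the tests say
  nothing about imputation under missing-not-at-random conditions.
- **Clinical covariates**: chemokine concentrations are log-normal with a
  per-unit-class log shift (IL-8 and PF-4 informative in the presets);
  gene-mutation status is ternary with class-*independent* prevalence, so
  gene columns are deliberately uninformative in the synthetic cohorts — a
  limitation to bear in mind when reading the merged-scenario results.
- **Survival**: exponential event times with per-class medians (controls 150,
  cancer 60, liver metastasis 24 months for disease-free survival; overall
  survival uses 1.5× those medians), uniform early censoring at rate 0.2.
  With no censoring the KM median converges to the configured median (tested
  within 15% at n = 500).
- **Determinism**: one root `SeedSequence` spawns a fixed sub-stream per
  component, so adding or reconfiguring one component never perturbs the
  draws of another, and equal seeds give bit-identical cohorts.

Cohort presets mirror realistic case/control sizes: 16/32/18 over 333
features (three-group), 13/13/11/12/10 over 289 (staging), 15/24/9 over 344
lipid features plus 9 clinical columns (merged scenario, 353 total).

Because planted effects are monotone and additive on the log scale, the true
class structure is essentially linear in the coded response — which is
exactly the regime the ordinal-regression design assumes. Passing tests
demonstrate correct mechanics and sane statistical behavior under these
conditions; they do not certify performance on real cohorts, where effect
sizes are smaller, features are correlated within lipid classes, and
missingness is structured.

## Preprocessing decisions

- "Scaling by 100,000" is implemented as division (bringing raw peak
  intensities to order-unity magnitudes appropriate for regularized
  regression); the factor is configurable.
- The replicate-outlier rule is made concrete as a leave-one-out z-score
  with k = 3 SD; groups with fewer than three present values are never
  masked. Decisions are computed simultaneously from the original values,
  so masking is order-invariant and never cascades.
- Missing intensities are imputed with the feature mean over **all** samples
  (never per class) so that imputation cannot leak class labels into the
  design; fully-missing features are dropped with a logged count.
- Gender enters as a single {0,1} indicator; continuous clinical covariates
  are z-scored by default so they are commensurate with scaled intensities.
- In the staging scenario, stage-0 cancers (no residual tumour) are excluded
  by default — the stage models are defined on codes 0 (controls) and I–IV —
  with a flag to include them as code 0.
- File-based runs infer replicate groups from the `<sample>_r<k>` identifier
  convention; identifiers without the suffix are treated as single
  measurements.

## Known limitations

- The p-values attached to selected coefficients are post-selection and
  unadjusted (documented above); cross-validated β selection is out of scope.
- The β scale is implementation-specific; panels, not β values, are the
  comparable quantity across implementations.
- The network uses a Gauss–Newton Hessian approximation in the evidence
  updates; γ is an estimate, reliable as a diagnostic but not a precise
  model-complexity measure near interpolation.
- The synthetic generator omits batch effects, within-class feature
  correlation, intensity-dependent missingness, and chromatographic
  artifacts beyond simple multiplicative spikes.
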