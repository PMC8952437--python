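# Methods

## The model

Tranexamic acid given intravenously to parturients in active hemorrhage is
described by a linear two-compartment disposition model with a double
first-order elimination from the central compartment. The 1-minute bolus is
modelled as a zero-order infusion (not an instantaneous bolus), so the peak
sits at the end of the infusion. Total central clearance CL (L/min) splits
into a urinary route — observed through cumulative urine collections — and
a non-urinary route; the split is the urinary excretion fraction
`p_urine`, with urinary micro-rate `k_urine = p_urine·CL/V1`. We
parameterise CL as the total clearance with `p_urine` as the split, rather
than two separate clearances, because the reported estimates pair CL with
`p_urine` and `k_urine` is then derived, never estimated directly.

The estimable structural family covers 1–3 compartments, single or dual
first-order central elimination, and (structurally) saturable
Michaelis–Menten routes and elimination from the first peripheral
compartment (a stand-in for loss through uterine hemorrhagic blood; no
observation stream attaches to it, so it exists as topology only). Linear
topologies are evaluated in closed form: the central amount after a unit
bolus is a sum of exponentials whose rates/weights come from the analytic
quadratic for two compartments and a batched eigendecomposition otherwise;
infusions and rescue doses superpose. Cumulative urinary output uses the
closed-form time-integral of the same exponentials. Saturable topologies
fall back to LSODA integration (rtol 1e-8); the closed forms and the ODE
path cross-check each other in the tests to 1e-6.

Hierarchical structure: individual parameters are log-normal around
covariate-adjusted typical values,

    log psi_il = log theta_l + sum_k beta_k x_ik + eta_il,  eta_il ~ N(0, omega_l²)

with a diagonal omega. `p_urine` is modelled on the logit scale by default
(`p_urine_transform="log"` restores a log-normal): a log-normal fraction
could exceed 1, and the reported between-subject variability (46%) makes
that a real possibility. Covariates enter either linearly on the log
(exponential relation, used for renal clearance on CL — deliberately
uncentred, matching the published final equation, even though the
intercept `theta_CL` then refers to eClcr = 0) or as a normalised power
(weight on V1, 70 kg reference).

Residual errors: plasma uses the combined model `g = sqrt(a1² + (b1·f)²)`,
urine the proportional model `g = b2·f`; additive and exponential models
are available (the exponential model is exactly additive on log
observations, with the Jacobian, which the tests verify). A urine
observation is the interval concentration `[Au(t_end) − Au(t_start)] /
volume` over a half-open collection interval; the source analysis never
states its urine observation equation, so this convention is an explicit
assumption of this package.

## Estimation

SAEM with Metropolis–Hastings conditional sampling. Defaults: 400
exploratory iterations (step size 1, simulated annealing limiting each
variance parameter to a 5% decay per iteration) then 200 smoothing
iterations (step size 1/(k−K1)); 5 MCMC chains; 2 componentwise
random-walk transitions per parameter per iteration with proposal scales
adapted toward ~30% acceptance (diminishing adaptation). Initial values
come from NCA-style heuristics (CL ≈ dose/AUC_inf, V1 ≈ dose/C_first,
`p_urine` from recovered urinary amount), omegas start at 0.30. Fixed
effects and covariate coefficients update by closed-form weighted least
squares on the stochastic sufficient statistics; the combined-error pair
(a1, b1) by a two-parameter Nelder–Mead on the smoothed residual
statistics; proportional errors in closed form. Reduced schedules (150–300
exploratory iterations, 2 chains) are used inside selection loops,
bootstraps and the test suite; they trade a little Monte Carlo noise for
speed and are stated where used.

The marginal −2LL is estimated by importance sampling (default ~2000
draws) with a multivariate t(5) proposal centred on each subject's
conditional mean and scaled by the Cholesky factor of the 1.2-inflated
conditional covariance. The correlated proposal matters: with a diagonal
proposal the weight variance differs systematically between nested models
and the Jensen bias of log-sum-exp can swamp a real likelihood-ratio
signal in BICc comparisons. Random effects with numerically zero variance
are excluded from the integral, which makes the no-variability limit
exact.

Standard errors and the condition number come from the expected Fisher
information of the linearized model: the model is linearized in the random
effects around the conditional means, giving a Gaussian marginal per
subject, and the information is assembled from finite-difference
derivatives of its mean and covariance (`F_jk = dm'S⁻¹dm +
½tr(S⁻¹dS_j S⁻¹dS_k)`). A score-outer-product (BHHH) estimator was tried
first and rejected: at a stochastic (not exactly optimal) estimate its
per-subject residual weighting is noisy enough to push the condition
number kappa across the 100 threshold on otherwise healthy fits. kappa is
the eigenvalue ratio of the correlation matrix of all estimates; with the
uncentred eClcr relation the theta_CL/beta_CL correlation is inherently
~0.93, so kappa ~30–60 is the healthy range and values in the hundreds
flag collinear covariate pairs.

BICc uses a hybrid penalty: parameters tied to random effects (fixed
effects, covariate coefficients, omegas) are penalised by log(N subjects),
residual-error parameters by log(total observations). Selection accepts a
candidate only with ΔBICc ≥ 3.84 (the chi-square(1) 5% point), kappa <
100, and Wald p ≤ 0.05, one candidate per round, ties broken by lowest
BICc then lowest kappa then label. Shrinkage is reported from the spread
of the conditional means across subjects (1 − var_i(E[eta_i|y])/omega²),
so rich individual data gives ~0% and uninformative data ~100%.

## Covariates

The candidate panel derives, per subject and twice (pre-pregnancy weight
and weight at caesarean): BMI, Devine ideal weight, adjusted weight
(IW + 0.4·(W − IW)), Janmahasatian female lean weight, Du Bois BSA,
Cockcroft–Gault creatinine clearance (female factor 0.85), and CKD-EPI
2009 / 4-variable MDRD eGFR. Serum creatinine is stored in mg/L (the
clinically reported scale here; ~6.5 mg/L = 0.65 mg/dL) and converted
inside the formulas. The eGFR formulas are weight-independent per
1.73 m²; the published baseline table nevertheless shows different values
for the two weight variants, which is only consistent with de-normalising
by the subject's BSA (eGFR·BSA/1.73) — that reading is adopted, making
eGFR weight-dependent through BSA.

## The synthetic trial generator

The generator emulates the study conditions: 34 + 45 subjects randomised
to 0.5 g / 1 g over 1 min; plasma samples at 15, 30, 60, 120, 180, 360 min
jittered uniformly ±10 min (never before end of infusion); two urine
collections over [0, 180] and (180, 360] min with log-normal volumes
(median 0.4 L, sdlog 0.4 — only "two urinary samples within 6 h" is
stated, so the intervals and volumes are this package's choices); rescue
second doses with probability 8/79 at a log-normal time (median 87 min,
sdlog 0.5), equal to the arm dose. Covariates are truncated normals at the
published per-arm means/SDs, with the location corrected for truncation
bias so sample means match the targets; the weight at caesarean adds an
independent truncated gain (mean 11 kg, SD 4 kg, from the published
marginal means — the true bw/bw_before correlation is unknown).
Observations are simulated from the published final-model estimates
(defaults of `GenerativeTruth`); negative noisy concentrations are
truncated at zero and counted rather than resampled, to keep the error
model honest.

What the generator does not emulate: assay quantification limits (no BLQ
data), time-varying covariates, within-subject occasion effects,
adjudicated bleeding outcomes (group labels in the NCA analysis are drawn
independently of exposure), and the one double-rescue subject. Passing
recovery tests therefore show that the estimation machinery is correct and
well calibrated under the stated design — not that the published model is
correct for real parturients.

## Noncompartmental analysis

Linear-up/log-down trapezoids (log on strictly declining positive
segments), with interval boundaries at exactly 1/30/60 min interpolated by
the same rule; C_T1 is obtained by log-linear back-extrapolation of the
earliest samples to the end of infusion. MRT is truncated to the observed
span (no extrapolation to infinity, given the 6-h design) and the terminal
half-life uses the last three declining points. Bleeding-status groups
(A: stopped by the assessment time; B: continuing; C: stopped then
re-bled; D at 60 min only) are compared by Kruskal–Wallis at 5%.

## Dose simulation

Monte Carlo cohorts (default 1000) draw covariates from the trial
generator, individual parameters from the final covariate model with
between-subject variability, and evaluate closed-form profiles on a 1-min
grid over 6 h. Threshold coverage (fraction maintaining ≥ c mg/L through a
window) is computed on true concentrations — residual assay error is
excluded by default and addable by flag, since coverage is a statement
about the subject's concentration, not about a measurement. The final
covariate model is simulated (not the covariate-free base model): it is
the only model whose between-subject variabilities are published; a
base-model simulation is available by passing `base_model()` with
user-supplied omegas. The published per-dose summary table's two rows are
internally inconsistent with the measured concentration ranges (the row
labelled 0.5 g carries 1 g magnitudes); this package always reports doses
explicitly and the tests use the dose-consistent association.

## Numerical choices and limitations

* Closed-form exponentials guard against coincident eigenrates and drop
  negligible-weight components when reporting terminal half-life (the
  Q → 0 limit otherwise yields an arbitrarily slow, zero-weight rate).
* SAEM is seeded end-to-end; identical seed and settings give bit-identical
  results. Bootstrap replicates and selection rounds derive their seeds
  from the caller's seed.
* Problem sizes in the shipped tests and drivers are scaled for a single
  CPU: 10-replicate recovery suites, 50-replicate bootstraps, 250–500
  simulation replicates for VPC/NPDE. These sizes are stated at each call
  site and are the package's choices.
* The bootstrap refits the final covariate structure only; it does not
  re-run covariate selection per replicate, so its intervals ignore
  model-selection uncertainty.
* No inter-occasion variability, no correlated random effects, no BLQ
  handling, no absorption models (IV only), and no multiple-testing
  correction in covariate screening (none is applied in the source
  procedure being mirrored).
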