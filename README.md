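# txapk

Population pharmacokinetics of intravenous tranexamic acid (TXA) in
hemorrhagic caesarean delivery.

TXA is an antifibrinolytic given as a 0.5 g or 1 g bolus over one minute to
parturients with postpartum hemorrhage (> 800 mL blood loss). Pregnancy and
active bleeding alter drug disposition — plasma volume expansion, elevated
renal filtration, ongoing blood loss — so healthy-volunteer kinetics do not
transfer. This package implements the full analysis chain for a two-arm PK
trial of this population: a compartmental model family with urinary output,
nonlinear mixed-effects estimation by SAEM, covariate forward selection,
simulation-based validation (VPC, NPDE, bootstrap), noncompartmental
analysis, and Monte Carlo dose simulation. Because the underlying clinical
dataset is not public, a synthetic-trial generator reproduces the study
design and the published population estimates, and every pipeline stage is
validated by recovering that known truth.

## Model

Plasma (mg/L) and urine observations follow a nonlinear mixed-effects model

    y_ij = f(t_ij, psi_i) + g(t_ij, psi_i) * eps_ij,   eps_ij ~ N(0, 1)

where `f` is a two-compartment disposition model with a double first-order
elimination from the central compartment: total clearance CL splits into a
urinary route (fraction `p_urine`, observed through cumulative urine
collections, k_urine = p_urine·CL/V1) and a non-urinary route. Structural
parameters (CL, V1, Q, V2, p_urine) are log-normally distributed between
subjects (p_urine on the logit scale so it stays in [0, 1]); plasma
residual error is combined (`sqrt(a1² + (b1·f)²)`), urine error
proportional (`b2·f`). Covariates act on the log scale:

    CL_i = theta_CL · exp(beta_CL · eClcr_i)          (Cockcroft–Gault, mL/min)
    V1_i = theta_V1 · (BWbef_i / 70)^beta_V1          (pre-pregnancy weight, kg)

Estimation is SAEM: Metropolis–Hastings sampling of the individual random
effects (5 chains) alternating with stochastic-approximation updates, an
exploratory phase with simulated annealing followed by a smoothing phase.
Model comparison uses a corrected BIC (hybrid subject/observation-count
penalty) with a 3.84-point improvement rule, a condition-number bound
(kappa < 100) and covariate Wald tests (p <= 0.05).

## Worked example

```python
from txapk import trial, saem

dataset, truth = trial.generate_trial(seed=1)   # 79 subjects, 34 x 0.5 g / 45 x 1 g
model = saem.PopulationModel(
    spec=trial.DUAL_2CMT,
    theta={"CL": 0.0, "V1": 0.0, "Q": 0.0, "V2": 0.0, "p_urine": 0.0},
    betas=[(trial.FINAL_RELATIONS[0], 0.0), (trial.FINAL_RELATIONS[1], 0.0)],
    omega={})
fit = saem.saem_fit(dataset, model, saem.SaemSettings(seed=42))
print({k: round(v, 3) for k, v in fit.model.theta.items()})
```

prints (seed 42 on the seed-1 trial)

```
{'CL': 0.072, 'V1': 10.104, 'Q': 0.284, 'V2': 9.195, 'p_urine': 0.546}
```

i.e. the clearance intercept (0.072 L/min at eClcr = 0), central volume at
the 70 kg reference (10.1 L), inter-compartmental clearance, peripheral
volume, and urinary excretion fraction (55% of elimination through urine),
recovered close to the generative values (0.077, 9.25, 0.32, 9.49, 0.54).

The numbered drivers under `analysis/` run the full study on a synthetic
trial and write tables under `results/`:

```
python analysis/01_simulate_trial.py      # trial + baseline characteristics
python analysis/02_fit_base_model.py      # structural model search by BICc
python analysis/03_covariate_selection.py # screening + forward selection
python analysis/04_validate_model.py      # VPC, NPDE, scaled bootstrap
python analysis/05_nca_analysis.py        # NCA + bleeding-group comparisons
python analysis/06_dose_simulation.py     # Monte Carlo dosing summaries
```

For example, `06_dose_simulation.py` reports that after a 1 g bolus the
simulated mean (10th–90th percentile) concentration at 15 min is
58.9 (37.0; 83.3) mg/L and 96% of 1000 virtual parturients stay at or above
30 mg/L throughout the first 15 minutes; after 0.5 g, 95% stay above
15 mg/L.

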