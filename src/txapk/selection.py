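"""Covariate screening and forward selection on the population PK model.

Candidates act on the log of a structural parameter either linearly
(log psi = log theta + beta x, the exponential relation) or as a normalised
power (log psi = log theta + beta log(x/ref), ref = 70 kg for weights). A
candidate is retained only when it lowers the corrected BIC by at least 3.84
points (the chi-square(1) 5% critical value), keeps the condition number
kappa below 100, and its coefficient is significant by a two-sided Wald test
at 5%. One candidate is added per round, best-first, until none qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .saem import (FitData, FitResult, PopulationModel, SaemSettings,
                   saem_fit, wald_test)
from .structural import CovariateRelation

__all__ = [
    "SelectionRules",
    "SelectionStep",
    "SelectionLedger",
    "screen_covariates",
    "forward_select",
    "default_candidates",
    "WEIGHT_COLUMNS",
]

WEIGHT_COLUMNS = {"BWBEF", "BW", "IW", "ABW_bef", "ABW", "LBW_bef", "LBW"}


@dataclass
class SelectionRules:
    delta_bicc: float = 3.84
    max_kappa: float = 100.0
    alpha_wald: float = 0.05


@dataclass
class SelectionStep:
    round: int
    candidate: str
    minus2LL: float
    bicc: float
    kappa: float
    wald_p: float
    accepted: bool
    reason: str


@dataclass
class SelectionLedger:
    steps: list[SelectionStep] = field(default_factory=list)
    accepted: list[CovariateRelation] = field(default_factory=list)
    base_bicc: float = float("nan")
    final_bicc: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def default_candidates(targets=("CL", "V1", "Q"), panel_columns=None,
                       include_power: bool = True) -> list[CovariateRelation]:
    """Systematic candidate set: every panel covariate on each target.

    Weight-like covariates additionally get the normalised power form with
    the 70 kg reference. The list can be restricted (e.g. to CL/V1/Q).
    """
    from .data import PANEL_COLUMNS
    cols = panel_columns or [c for c in PANEL_COLUMNS if c != "HT"]
    out = []
    for t in targets:
        for c in cols:
            out.append(CovariateRelation(t, c, "linear"))
            if include_power and c in WEIGHT_COLUMNS:
                out.append(CovariateRelation(t, c, "power", ref=70.0))
    return out


def screen_covariates(fit: FitResult, candidates=None) -> pd.DataFrame:
    """Rank candidate covariate-parameter pairs by regression on the EBEs.

    The log (or logit) individual parameter, reconstructed from the
    conditional-mean random effects, is regressed on each candidate's design
    value; rows are ranked by r^2 within each target parameter. Constant
    covariates are skipped with a note.
    """
    fitdata = fit.fitdata
    model = fit.model
    panel = fitdata.panel
    names = model.param_names()
    candidates = candidates or default_candidates()
    psi = fit.individual_parameters()
    rows = []
    for rel in candidates:
        if rel.target not in names:
            continue
        x = np.asarray(rel.design_value(panel[rel.covariate].to_numpy(dtype=float)))
        y = model.to_transformed(rel.target, psi[rel.target])
        if np.ptp(x) == 0:
            rows.append({"target": rel.target, "covariate": rel.label(),
                         "r2": np.nan, "p": np.nan, "note": "constant covariate"})
            continue
        res = stats.linregress(x, y)
        rows.append({"target": rel.target, "covariate": rel.label(),
                     "r2": res.rvalue ** 2, "p": res.pvalue, "note": ""})
    df = pd.DataFrame(rows)
    return df.sort_values(["target", "r2"], ascending=[True, False]).reset_index(drop=True)


def _fit_with(fitdata: FitData, base: PopulationModel,
              relations: list[CovariateRelation], settings: SaemSettings,
              warm: PopulationModel | None = None) -> FitResult:
    start = warm or base
    model = PopulationModel(
        spec=base.spec,
        theta=dict(start.theta),
        betas=[(rel, next((b for r, b in start.betas if r == rel), 0.0))
               for rel in relations],
        omega=dict(start.omega),
        error_plasma=dict(start.error_plasma),
        error_urine=dict(start.error_urine),
        p_urine_transform=base.p_urine_transform,
    )
    return saem_fit(fitdata, model, settings)


def forward_select(dataset, base_model: PopulationModel,
                   candidates: list[CovariateRelation],
                   rules: SelectionRules | None = None,
                   settings: SaemSettings | None = None,
                   base_fit: FitResult | None = None):
    """One-at-a-time forward covariate selection.

    Returns (SelectionLedger, final FitResult). Candidate fits that fail are
    recorded as non-evaluable and selection continues. The ledger is
    deterministic for a fixed settings seed.
    """
    rules = rules or SelectionRules()
    settings = settings or SaemSettings(n_explore=200, n_smooth=100, n_chains=2,
                                        ll_draws=1000)
    fitdata = dataset if isinstance(dataset, FitData) else FitData(dataset)
    ledger = SelectionLedger()

    if base_fit is None:
        base_fit = _fit_with(fitdata, base_model, [], settings)
    current_fit = base_fit
    ledger.base_bicc = base_fit.bicc
    remaining = list(candidates)
    accepted: list[CovariateRelation] = []
    rnd = 0

    while remaining:
        rnd += 1
        evaluated = []
        for rel in remaining:
            label = rel.label()
            try:
                cand_settings = replace(settings, seed=settings.seed + 101 * rnd)
                fit = _fit_with(fitdata, base_model, accepted + [rel],
                                cand_settings, warm=current_fit.model)
                beta = next(b for r, b in fit.model.betas if r == rel)
                se = fit.se.get(f"beta_{rel.target}_{rel.covariate}", np.nan)
                p = wald_test(beta, se) if np.isfinite(se) and se > 0 else np.nan
                step = SelectionStep(rnd, label, fit.minus2LL, fit.bicc,
                                     fit.kappa, p, False, "")
                evaluated.append((step, rel, fit))
            except Exception as exc:  # noqa: BLE001 - recorded, selection continues
                ledger.steps.append(SelectionStep(
                    rnd, label, np.nan, np.nan, np.nan, np.nan, False,
                    f"non-evaluable: {exc}"))

        qualifying = []
        for step, rel, fit in evaluated:
            dbic = current_fit.bicc - step.bicc
            if dbic < rules.delta_bicc:
                step.reason = f"dBICc {dbic:.2f} < {rules.delta_bicc}"
            elif not (step.kappa < rules.max_kappa):
                step.reason = f"kappa {step.kappa:.1f} >= {rules.max_kappa} (over-parameterised)"
            elif not (step.wald_p <= rules.alpha_wald):
                step.reason = f"Wald p {step.wald_p:.3g} > {rules.alpha_wald}"
            else:
                qualifying.append((step, rel, fit))

        if not qualifying:
            ledger.steps.extend(s for s, _, _ in evaluated)
            break
        qualifying.sort(key=lambda q: (q[0].bicc, q[0].kappa, q[0].candidate))
        best_step, best_rel, best_fit = qualifying[0]
        for step, _, _ in qualifying[1:]:
            step.reason = "qualified, not best this round"
        best_step.accepted = True
        best_step.reason = "accepted"
        ledger.steps.extend(s for s, _, _ in evaluated)
        accepted.append(best_rel)
        remaining = [r for r in remaining if r is not best_rel]
        current_fit = best_fit

    ledger.accepted = accepted
    ledger.final_bicc = current_fit.bicc
    return ledger, current_fit
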