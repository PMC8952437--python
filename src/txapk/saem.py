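"""Nonlinear mixed-effects estimation by SAEM with MCMC conditional sampling.

The population model is hierarchical: individual structural parameters are
log-normally distributed around covariate-adjusted typical values
(log psi_i = log theta + sum beta x_i + eta_i, eta_i ~ N(0, omega^2), diagonal
omega), except the urinary excretion fraction which is modelled on the logit
scale by default so that it stays in [0, 1]. Observations are plasma
concentrations with a combined (additive + proportional) residual error and
urine interval concentrations with a proportional error:

    y_ij = f(t_ij, psi_i) + g(t_ij, psi_i) eps_ij,   eps_ij ~ N(0, 1)

Estimation alternates Metropolis-Hastings sampling of the eta_i (several
independent chains) with stochastic-approximation updates of the
complete-data sufficient statistics: an exploratory phase with step size 1
and simulated annealing on the variance parameters, then a smoothing phase
with step size 1/(k - K1). The marginal -2 log-likelihood is estimated by
importance sampling around the conditional distributions, and standard
errors come from a linearized (FOCE-like) Fisher information matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

from .data import PKDataset, covariate_table
from .structural import CovariateRelation, StructuralSpec, batch_disposition, \
    _infusion_shape, _infusion_shape_integral

__all__ = [
    "PopulationModel",
    "SaemSettings",
    "FitResult",
    "FitData",
    "saem_fit",
    "log_likelihood",
    "compute_bicc",
    "fisher_information",
    "shrinkage",
    "wald_test",
    "shapiro_wilk_check",
    "simulate_observations",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Population model
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Structural spec + fixed effects + covariate effects + variability."""

    spec: StructuralSpec
    theta: dict[str, float]
    betas: list[tuple[CovariateRelation, float]] = field(default_factory=list)
    omega: dict[str, float] = field(default_factory=dict)
    error_plasma: dict = field(default_factory=lambda: {"model": "combined", "a": 0.5, "b": 0.2})
    error_urine: dict = field(default_factory=lambda: {"model": "proportional", "b": 0.3})
    p_urine_transform: str = "logit"  # or "log"

    def __post_init__(self) -> None:
        names = self.param_names()
        for name in names:
            if name not in self.theta:
                raise ValueError(f"missing fixed effect {name}")
        self.omega = {name: float(self.omega.get(name, 0.0)) for name in names}
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("omega must be non-negative")
        for rel, _ in self.betas:
            if rel.target not in names:
                raise ValueError(f"covariate targets unknown parameter {rel.target}")

    def param_names(self) -> list[str]:
        if not self.spec.is_linear:
            raise ValueError("only linear structural specs are estimable")
        return self.spec.param_names()

    def transform(self, name: str) -> str:
        if name == "p_urine" and self.p_urine_transform == "logit":
            return "logit"
        return "log"

    def to_transformed(self, name: str, value):
        return logit(value) if self.transform(name) == "logit" else np.log(value)

    def to_natural(self, name: str, value):
        return expit(value) if self.transform(name) == "logit" else np.exp(value)

    def betas_for(self, name: str) -> list[tuple[CovariateRelation, float]]:
        return [(rel, b) for rel, b in self.betas if rel.target == name]

    def n_pop_parameters(self) -> tuple[int, int]:
        """(number of random-effect-linked parameters, number of residual parameters)."""
        n_rand = sum(1 + len(self.betas_for(n)) + 1 for n in self.param_names())
        n_res = sum(
            {"additive": 1, "proportional": 1, "exponential": 1, "combined": 2}[e["model"]]
            for e in (self.error_plasma, self.error_urine)
        )
        return n_rand, n_res


# ---------------------------------------------------------------------------
# Fit-ready data arrays
# ---------------------------------------------------------------------------

class FitData:
    """Flat, pair-indexed arrays for fast vectorised model evaluation.

    Every (dose, evaluation-time) pair of the same subject is enumerated
    once; predictions are superposed dose contributions accumulated with
    ``bincount``. Urine interval concentrations use two evaluation rows
    (interval start and end) of the cumulative urine-amount curve.
    """

    def __init__(self, dataset: PKDataset, panel=None):
        self.dataset = dataset
        self.ids = [s.id for s in dataset.subjects]
        self.idx = {sid: i for i, sid in enumerate(self.ids)}
        self.n_sub = len(self.ids)
        self.arm = np.array([s.arm for s in dataset.subjects])
        self.panel = covariate_table(dataset) if panel is None else panel

        d_sub = np.array([self.idx[d.subject] for d in dataset.doses])
        d_time = np.array([d.time for d in dataset.doses], dtype=float)
        d_amt = np.array([d.amount for d in dataset.doses], dtype=float)
        d_dur = np.array([d.infusion_duration for d in dataset.doses], dtype=float)

        plasma = [o for o in dataset.observations if o.kind == "plasma"]
        urine = [o for o in dataset.observations if o.kind == "urine"]
        self.y_plasma = np.array([o.value for o in plasma], dtype=float)
        self.y_urine = np.array([o.value for o in urine], dtype=float)
        self.p_sub = np.array([self.idx[o.subject] for o in plasma], dtype=int)
        self.u_sub = np.array([self.idx[o.subject] for o in urine], dtype=int)
        self.uvol = np.array([o.urine_volume for o in urine], dtype=float)
        self.n_plasma = len(plasma)
        self.n_urine = len(urine)
        self.n_obs = self.n_plasma + self.n_urine

        tC = np.array([o.time for o in plasma], dtype=float)
        tU = np.empty(2 * self.n_urine)
        sU = np.empty(2 * self.n_urine, dtype=int)
        for i, o in enumerate(urine):
            tU[2 * i] = o.interval_start
            tU[2 * i + 1] = o.time
            sU[2 * i] = sU[2 * i + 1] = self.idx[o.subject]

        def pairs(t_eval, s_eval):
            pd, pe = [], []
            for j in range(len(d_sub)):
                hit = np.nonzero((s_eval == d_sub[j]) & (t_eval > d_time[j]))[0]
                pd.extend([j] * len(hit))
                pe.extend(hit.tolist())
            pd = np.array(pd, dtype=int)
            pe = np.array(pe, dtype=int)
            return {
                "sub": d_sub[pd],
                "dt": t_eval[pe] - d_time[pd],
                "rate": d_amt[pd] / d_dur[pd],
                "dur": d_dur[pd],
                "eval": pe,
            }

        self.pairC = pairs(tC, self.p_sub)
        self.pairU = pairs(tU, sU)
        self.d_sub, self.d_time, self.d_amt, self.d_dur = d_sub, d_time, d_amt, d_dur
        self.dose_total = np.bincount(d_sub, weights=d_amt, minlength=self.n_sub)

    def design_matrix(self, model: PopulationModel, name: str) -> np.ndarray:
        cols = [np.ones(self.n_sub)]
        for rel, _ in model.betas_for(name):
            x = self.panel[rel.covariate].to_numpy(dtype=float)
            cols.append(np.asarray(rel.design_value(x), dtype=float))
        return np.column_stack(cols)

    # -- structural prediction -------------------------------------------

    def predict(self, model: PopulationModel, psi: dict[str, np.ndarray]):
        """(plasma predictions, urine interval-concentration predictions)."""
        spec = model.spec
        a, w = batch_disposition(spec, psi)
        V1 = psi["V1"]
        pur = psi.get("p_urine", np.ones(self.n_sub))
        ku_over_rate = pur * psi["CL"] / V1  # k_urine = p * CL / V1

        pc = self.pairC
        s = pc["sub"]
        shape = _infusion_shape(a[s], pc["dt"][:, None], pc["dur"][:, None])
        contrib = pc["rate"] / V1[s] * np.einsum("ij,ij->i", w[s], shape)
        f_plasma = np.bincount(pc["eval"], weights=contrib, minlength=self.n_plasma)

        pu = self.pairU
        s = pu["sub"]
        integ = _infusion_shape_integral(a[s], pu["dt"][:, None], pu["dur"][:, None])
        contrib = ku_over_rate[s] * pu["rate"] * np.einsum("ij,ij->i", w[s], integ)
        au = np.bincount(pu["eval"], weights=contrib, minlength=2 * self.n_urine)
        f_urine = (au[1::2] - au[0::2]) / self.uvol
        return f_plasma, np.maximum(f_urine, 0.0)


# ---------------------------------------------------------------------------
# Residual error models
# ---------------------------------------------------------------------------

def _error_sd(error: dict, f: np.ndarray) -> np.ndarray:
    m = error["model"]
    if m == "additive":
        g = np.full_like(f, error["a"])
    elif m == "proportional":
        g = error["b"] * np.abs(f)
    elif m == "combined":
        g = np.sqrt(error["a"] ** 2 + (error["b"] * f) ** 2)
    else:
        raise ValueError(f"unknown error model {m}")
    return np.maximum(g, 1e-10)


def _obs_loglik(y: np.ndarray, f: np.ndarray, error: dict) -> np.ndarray:
    """Per-observation log-density of y given the prediction f."""
    if error["model"] == "exponential":
        # y = f * exp(a eps): additive on the log scale, with Jacobian
        fl = np.log(np.maximum(f, 1e-12))
        yl = np.log(np.maximum(y, 1e-12))
        a = max(error["a"], 1e-10)
        return -0.5 * (((yl - fl) / a) ** 2 + _LOG2PI) - math.log(a) - yl
    g = _error_sd(error, f)
    return -0.5 * (((y - f) / g) ** 2 + _LOG2PI) - np.log(g)


def _error_n_params(error: dict) -> int:
    return 2 if error["model"] == "combined" else 1


# ---------------------------------------------------------------------------
# Settings / results
# ---------------------------------------------------------------------------

@dataclass
class SaemSettings:
    n_explore: int = 400
    n_smooth: int = 200
    n_chains: int = 5
    n_transitions: int = 2
    seed: int = 0
    anneal: float = 0.95
    n_conditional: int = 120
    n_conditional_burn: int = 40
    ll_draws: int = 2000
    compute_fim: bool = True
    compute_ll: bool = True


@dataclass
class FitResult:
    model: PopulationModel
    rse: dict[str, float]
    minus2LL: float
    bicc: float
    kappa: float
    shrinkage: dict[str, float]
    etas: np.ndarray              # conditional means, (n_sub, P)
    eta_sd: np.ndarray            # conditional SDs, (n_sub, P)
    eta_draws: np.ndarray         # (n_keep, n_sub, P) pooled conditional draws
    se: dict[str, float]
    trace: dict[str, list]
    settings: SaemSettings
    fitdata: FitData
    ll_se: float = float("nan")
    covariance: np.ndarray | None = None
    pvec_names: list[str] | None = None
    eta_cov: np.ndarray | None = None  # conditional covariances, (n_sub, P, P)

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names()

    def individual_parameters(self) -> dict[str, np.ndarray]:
        """Empirical-Bayes individual parameters (conditional means of eta)."""
        return _natural_psi(self.model, self.fitdata, self.etas)


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------

def _mu_matrix(model: PopulationModel, fitdata: FitData,
               gamma: dict[str, np.ndarray]) -> np.ndarray:
    names = model.param_names()
    mu = np.empty((fitdata.n_sub, len(names)))
    for j, name in enumerate(names):
        C = fitdata.design_matrix(model, name)
        mu[:, j] = C @ gamma[name]
    return mu


def _phi_to_psi(model: PopulationModel, phi: np.ndarray) -> dict[str, np.ndarray]:
    names = model.param_names()
    psi = {}
    for j, name in enumerate(names):
        psi[name] = model.to_natural(name, phi[:, j])
    return psi


def _natural_psi(model: PopulationModel, fitdata: FitData, etas: np.ndarray):
    gamma = _gamma_from_model(model, fitdata)
    mu = _mu_matrix(model, fitdata, gamma)
    return _phi_to_psi(model, mu + etas)


def _gamma_from_model(model: PopulationModel, fitdata: FitData) -> dict[str, np.ndarray]:
    gamma = {}
    for name in model.param_names():
        g = [float(model.to_transformed(name, model.theta[name]))]
        g += [b for _, b in model.betas_for(name)]
        gamma[name] = np.array(g)
    return gamma


def _model_from_gamma(model: PopulationModel, gamma, omega2, err_p, err_u) -> PopulationModel:
    theta = {}
    betas = []
    for name in model.param_names():
        theta[name] = float(model.to_natural(name, gamma[name][0]))
        for k, (rel, _) in enumerate(model.betas_for(name)):
            betas.append((rel, float(gamma[name][k + 1])))
    omega = {n: float(np.sqrt(omega2[n])) for n in model.param_names()}
    return PopulationModel(
        spec=model.spec, theta=theta, betas=betas, omega=omega,
        error_plasma=dict(err_p), error_urine=dict(err_u),
        p_urine_transform=model.p_urine_transform,
    )


def _subject_loglik(model, fitdata, psi) -> np.ndarray:
    fp, fu = fitdata.predict(model, psi)
    llp = _obs_loglik(fitdata.y_plasma, fp, model.error_plasma)
    llu = _obs_loglik(fitdata.y_urine, fu, model.error_urine)
    out = np.bincount(fitdata.p_sub, weights=llp, minlength=fitdata.n_sub)
    out += np.bincount(fitdata.u_sub, weights=llu, minlength=fitdata.n_sub)
    return out


def _initial_values(model: PopulationModel, fitdata: FitData) -> dict[str, float]:
    """NCA-informed heuristic initial fixed effects."""
    ds = fitdata.dataset
    cl0, v10, p0 = [], [], []
    for sid in fitdata.ids:
        i = fitdata.idx[sid]
        t = np.array([o.time for o in ds.observations
                      if o.subject == sid and o.kind == "plasma"])
        c = np.array([o.value for o in ds.observations
                      if o.subject == sid and o.kind == "plasma"])
        dose = fitdata.dose_total[i]
        if len(t) >= 3 and np.all(c > 0):
            auc = np.trapezoid(c, t)
            lam = max(1e-4, -np.polyfit(t[-3:], np.log(c[-3:]), 1)[0])
            auc_inf = auc + c[-1] / lam
            cl0.append(dose / auc_inf)
            v10.append(dose / c[0])
        amt_u = sum(o.value * o.urine_volume for o in ds.observations
                    if o.subject == sid and o.kind == "urine")
        if dose > 0:
            p0.append(min(0.95, max(0.05, amt_u / dose)))
    cl = float(np.median(cl0)) if cl0 else 0.1
    v1 = float(np.median(v10)) if v10 else 10.0
    init = {"CL": cl, "V1": max(v1, 1.0)}
    if model.spec.n_compartments >= 2:
        init["Q"] = 0.5 * cl + 0.05
        init["V2"] = max(v1, 1.0)
    if model.spec.n_compartments == 3:
        init["Q2"] = 0.25 * cl + 0.02
        init["V3"] = max(v1, 1.0)
    if "p_urine" in model.param_names():
        init["p_urine"] = float(np.median(p0)) if p0 else 0.5
    return init


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------

def saem_fit(dataset: PKDataset, model: PopulationModel,
             settings: SaemSettings | None = None) -> FitResult:
    """Fit a population model by SAEM; reproducible under a fixed seed."""
    settings = settings or SaemSettings()
    fitdata = dataset if isinstance(dataset, FitData) else FitData(dataset)
    if fitdata.n_sub < 2:
        raise ValueError("SAEM needs at least 2 subjects")
    rng = np.random.default_rng(settings.seed)
    names = model.param_names()
    P = len(names)
    L = settings.n_chains

    # --- initial state
    theta0 = dict(_initial_values(model, fitdata))
    theta0.update({k: v for k, v in model.theta.items() if v > 0})
    init_model = replace(model)
    init_model.theta = {n: theta0[n] for n in names}
    gamma = _gamma_from_model(init_model, fitdata)
    omega2 = {n: (model.omega.get(n) or 0.3) ** 2 for n in names}
    err_p = dict(model.error_plasma)
    err_u = dict(model.error_urine)
    err_p.setdefault("a", 0.5)
    err_p.setdefault("b", 0.2)
    err_u.setdefault("b", 0.3)

    CtC = {n: fitdata.design_matrix(model, n).T @ fitdata.design_matrix(model, n)
           for n in names}
    Cmat = {n: fitdata.design_matrix(model, n) for n in names}

    eta = np.zeros((L, fitdata.n_sub, P))
    sig = np.full(P, 0.4)
    acc_hist = np.zeros(P)
    prop_hist = np.zeros(P)

    cur_model = _model_from_gamma(init_model, gamma, omega2, err_p, err_u)
    mu = _mu_matrix(cur_model, fitdata, gamma)
    ll_cache = np.stack([
        _subject_loglik(cur_model, fitdata, _phi_to_psi(cur_model, mu + eta[c]))
        for c in range(L)
    ])

    # sufficient statistics (stochastic approximations)
    T1 = {n: np.zeros(CtC[n].shape[0]) for n in names}
    T2 = {n: 0.0 for n in names}
    s_res_p = np.zeros(fitdata.n_plasma)
    s_f2_p = np.ones(fitdata.n_plasma)
    s_rel_u = np.zeros(fitdata.n_urine)

    trace: dict[str, list] = {n: [] for n in names}
    trace.update({f"omega_{n}": [] for n in names})
    trace.update({"a1": [], "b1": [], "b2": []})

    K_total = settings.n_explore + settings.n_smooth
    omega_floor = 1e-6

    for k in range(1, K_total + 1):
        explore = k <= settings.n_explore
        step = 1.0 if explore else 1.0 / (k - settings.n_explore)

        # --- MCMC: MH sweeps per chain
        for c in range(L):
            for _ in range(settings.n_transitions):
                for pi in range(P):
                    prop = eta[c].copy()
                    prop[:, pi] += sig[pi] * rng.standard_normal(fitdata.n_sub)
                    psi = _phi_to_psi(cur_model, mu + prop)
                    ll = _subject_loglik(cur_model, fitdata, psi)
                    dprior = (eta[c][:, pi] ** 2 - prop[:, pi] ** 2) / (2.0 * max(omega2[names[pi]], omega_floor))
                    logr = ll - ll_cache[c] + dprior
                    accept = np.log(rng.uniform(size=fitdata.n_sub)) < logr
                    eta[c][accept, pi] = prop[accept, pi]
                    ll_cache[c][accept] = ll[accept]
                    acc_hist[pi] += accept.mean()
                    prop_hist[pi] += 1.0

        # adapt proposal scales towards ~30% acceptance (diminishing)
        rate = acc_hist / np.maximum(prop_hist, 1.0)
        gain = min(0.4, 4.0 / k)
        sig *= np.exp(gain * (rate - 0.3))
        sig = np.clip(sig, 1e-3, 5.0)
        acc_hist[:] = 0.0
        prop_hist[:] = 0.0

        # --- E-step statistics (averaged over chains)
        t1_new = {n: np.zeros_like(T1[n]) for n in names}
        t2_new = {n: 0.0 for n in names}
        res_p = np.zeros(fitdata.n_plasma)
        f2_p = np.zeros(fitdata.n_plasma)
        rel_u = np.zeros(fitdata.n_urine)
        for c in range(L):
            phi = mu + eta[c]
            psi = _phi_to_psi(cur_model, phi)
            fp, fu = fitdata.predict(cur_model, psi)
            res_p += (fitdata.y_plasma - fp) ** 2
            f2_p += fp ** 2
            fu_safe = np.maximum(fu, 1e-8)
            if err_u["model"] == "exponential":
                rel_u += (np.log(np.maximum(fitdata.y_urine, 1e-12)) - np.log(fu_safe)) ** 2
            else:
                rel_u += (fitdata.y_urine - fu) ** 2 / fu_safe ** 2
            for j, n in enumerate(names):
                t1_new[n] += Cmat[n].T @ phi[:, j]
                t2_new[n] += float(phi[:, j] @ phi[:, j])
        for n in names:
            t1_new[n] /= L
            t2_new[n] /= L
        res_p /= L
        f2_p /= L
        rel_u /= L

        for n in names:
            T1[n] += step * (t1_new[n] - T1[n])
            T2[n] += step * (t2_new[n] - T2[n])
        s_res_p += step * (res_p - s_res_p)
        s_f2_p += step * (f2_p - s_f2_p)
        s_rel_u += step * (rel_u - s_rel_u)

        # --- M-step
        for n in names:
            g = np.linalg.solve(CtC[n], T1[n])
            resid = T2[n] - 2.0 * g @ T1[n] + g @ CtC[n] @ g
            om2 = max(resid / fitdata.n_sub, omega_floor)
            if explore:
                om2 = max(om2, settings.anneal * omega2[n])
            gamma[n] = g
            omega2[n] = om2
            if not np.all(np.isfinite(g)):
                raise RuntimeError(f"SAEM diverged: non-finite update for {n}")

        err_p = _update_error_plasma(err_p, s_res_p, s_f2_p,
                                     settings.anneal if explore else None)
        err_u = _update_error_urine(err_u, s_rel_u,
                                    settings.anneal if explore else None)

        cur_model = _model_from_gamma(init_model, gamma, omega2, err_p, err_u)
        mu = _mu_matrix(cur_model, fitdata, gamma)
        # refresh cached log-likelihoods under the new parameters
        for c in range(L):
            ll_cache[c] = _subject_loglik(
                cur_model, fitdata, _phi_to_psi(cur_model, mu + eta[c])
            )

        for n in names:
            trace[n].append(cur_model.theta[n])
            trace[f"omega_{n}"].append(math.sqrt(omega2[n]))
        trace["a1"].append(err_p.get("a", float("nan")))
        trace["b1"].append(err_p.get("b", float("nan")))
        trace["b2"].append(err_u.get("b", err_u.get("a", float("nan"))))

    # --- conditional distribution sampling at the final estimates
    draws = []
    for it in range(settings.n_conditional):
        for c in range(L):
            for pi in range(P):
                prop = eta[c].copy()
                prop[:, pi] += sig[pi] * rng.standard_normal(fitdata.n_sub)
                psi = _phi_to_psi(cur_model, mu + prop)
                ll = _subject_loglik(cur_model, fitdata, psi)
                dprior = (eta[c][:, pi] ** 2 - prop[:, pi] ** 2) / (2.0 * max(omega2[names[pi]], omega_floor))
                accept = np.log(rng.uniform(size=fitdata.n_sub)) < ll - ll_cache[c] + dprior
                eta[c][accept, pi] = prop[accept, pi]
                ll_cache[c][accept] = ll[accept]
        if it >= settings.n_conditional_burn:
            draws.append(eta.copy())
    eta_draws = np.concatenate(draws, axis=0)  # (n_keep*L, n_sub, P)
    cond_mean = eta_draws.mean(axis=0)
    cond_sd = eta_draws.std(axis=0) + 1e-12
    centred = eta_draws - cond_mean[None]
    cond_cov = np.einsum("kip,kiq->ipq", centred, centred) / max(len(eta_draws) - 1, 1)
    cond_cov += 1e-12 * np.eye(P)[None]

    # shrinkage from the spread of the conditional means across subjects:
    # with rich individual data the means recover the true etas (0%), with
    # uninformative data they collapse to the population mean (100%)
    shr = {}
    for j, n in enumerate(names):
        if omega2[n] <= omega_floor * 2:
            shr[n] = float("nan")
        else:
            shr[n] = 100.0 * (1.0 - cond_mean[:, j].var() / omega2[n])

    result = FitResult(
        model=cur_model, rse={}, minus2LL=float("nan"), bicc=float("nan"),
        kappa=float("nan"), shrinkage=shr, etas=cond_mean, eta_sd=cond_sd,
        eta_draws=eta_draws[:: max(1, len(eta_draws) // 200)],
        se={}, trace=trace, settings=settings, fitdata=fitdata,
        eta_cov=cond_cov,
    )

    if settings.compute_ll:
        m2ll, se = log_likelihood(fitdata, cur_model, result, settings.ll_draws,
                                  seed=settings.seed + 1)
        result.minus2LL = m2ll
        result.ll_se = se
        result.bicc = compute_bicc(m2ll, cur_model, fitdata)
    if settings.compute_fim:
        fisher_information(fitdata, cur_model, result)
    return result


def _update_error_plasma(err, s_res, s_f2, anneal):
    m = err["model"]
    new = dict(err)
    if s_res.size == 0:
        return new
    if m in ("additive", "exponential"):
        a2 = float(np.mean(s_res))
        if anneal is not None:
            a2 = max(a2, (anneal * err["a"]) ** 2)
        new["a"] = math.sqrt(max(a2, 1e-12))
        return new
    if m == "proportional":
        b2 = float(np.mean(s_res / np.maximum(s_f2, 1e-12)))
        if anneal is not None:
            b2 = max(b2, (anneal * err["b"]) ** 2)
        new["b"] = math.sqrt(max(b2, 1e-12))
        return new
    # combined: 2-parameter pseudo-likelihood minimisation on the SA statistics
    def q(logab):
        a2 = math.exp(2 * logab[0])
        b2 = math.exp(2 * logab[1])
        g2 = a2 + b2 * s_f2
        return float(np.sum(np.log(g2) + s_res / g2))

    x0 = [math.log(max(err["a"], 1e-4)), math.log(max(err["b"], 1e-4))]
    res = optimize.minimize(q, x0, method="Nelder-Mead",
                            options={"maxiter": 80, "xatol": 1e-4, "fatol": 1e-8})
    a, b = math.exp(res.x[0]), math.exp(res.x[1])
    if anneal is not None:
        a = max(a, anneal * err["a"])
        b = max(b, anneal * err["b"])
    new["a"], new["b"] = a, b
    return new


def _update_error_urine(err, s_rel, anneal):
    new = dict(err)
    if s_rel.size == 0:
        return new
    key = "a" if err["model"] in ("additive", "exponential") else "b"
    v2 = float(np.mean(s_rel))
    if anneal is not None:
        v2 = max(v2, (anneal * err[key]) ** 2)
    new[key] = math.sqrt(max(v2, 1e-12))
    return new


# ---------------------------------------------------------------------------
# Likelihood, information and derived metrics
# ---------------------------------------------------------------------------

def log_likelihood(fitdata: FitData, model: PopulationModel, fit: FitResult,
                   mc_size: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Importance-sampling estimate of the marginal -2 log-likelihood.

    The proposal is a multivariate t(5) per subject centred on the
    conditional mean of eta, scaled by the Cholesky factor of the (slightly
    inflated) conditional covariance when available, falling back to the
    diagonal conditional SDs. Returns (-2LL, Monte Carlo standard error of
    -2LL).
    """
    rng = np.random.default_rng(seed)
    names = model.param_names()
    P = len(names)
    n = fitdata.n_sub
    gamma = _gamma_from_model(model, fitdata)
    mu = _mu_matrix(model, fitdata, gamma)
    om = np.array([max(model.omega[nm], 1e-8) for nm in names])
    # random effects with (numerically) zero variance contribute no integral
    # dimension: they are fixed at zero so the estimate is exact for them
    active = np.array([model.omega[nm] > 1e-8 for nm in names])
    centre = np.where(active, fit.etas, 0.0)
    df = 5.0

    eta_cov = getattr(fit, "eta_cov", None)
    use_corr = eta_cov is not None and bool(np.all(active))
    if use_corr:
        try:
            L = np.linalg.cholesky(1.2 * eta_cov)     # (n, P, P)
            logdetL = np.log(np.abs(np.einsum("ijj->ij", L))).sum(axis=1)
        except np.linalg.LinAlgError:
            use_corr = False
    if not use_corr:
        scale = np.maximum(fit.eta_sd, 1e-8) * 1.1

    logw = np.empty((mc_size, n))
    for m in range(mc_size):
        z = rng.standard_t(df, size=(n, P)) * active
        if use_corr:
            etam = centre + np.einsum("ipq,iq->ip", L, z)
            lq = np.sum(stats.t.logpdf(z, df), axis=1) - logdetL
        else:
            etam = centre + scale * z * active
            lq = np.sum((stats.t.logpdf(z, df) - np.log(scale))[:, active], axis=1)
        psi = _phi_to_psi(model, mu + etam)
        ll = _subject_loglik(model, fitdata, psi)
        lprior = np.sum((-0.5 * (etam / om) ** 2 - np.log(om) - 0.5 * _LOG2PI)[:, active],
                        axis=1)
        logw[m] = ll + lprior - lq
    li = logsumexp(logw, axis=0) - math.log(mc_size)
    m2ll = float(-2.0 * np.sum(li))
    # per-subject MC error of log-mean-weight, delta method
    w = np.exp(logw - li[None, :])
    var_li = w.var(axis=0) / mc_size
    se = float(2.0 * math.sqrt(np.sum(var_li)))
    return m2ll, se


def compute_bicc(minus2LL: float, model: PopulationModel, fitdata) -> float:
    """Corrected BIC with a hybrid sample-size penalty.

    Population parameters attached to random effects (fixed effects, their
    covariate coefficients, and the omegas) are penalised by log(N subjects);
    residual-error parameters by log(total observations).
    """
    n_rand, n_res = model.n_pop_parameters()
    N = fitdata.n_sub
    n_tot = fitdata.n_obs if hasattr(fitdata, "n_obs") else len(fitdata.observations)
    return float(minus2LL + n_rand * math.log(N) + n_res * math.log(n_tot))


def _pvec_pack(model: PopulationModel, fitdata: FitData):
    """Flatten all population parameters into one vector for the FIM."""
    names = model.param_names()
    gamma = _gamma_from_model(model, fitdata)
    vec, labels = [], []
    for n in names:
        vec.append(gamma[n][0])
        labels.append(f"theta_{n}")
        for k, (rel, b) in enumerate(model.betas_for(n)):
            vec.append(b)
            labels.append(f"beta_{n}_{rel.covariate}")
    for n in names:
        vec.append(math.log(max(model.omega[n], 1e-8)))
        labels.append(f"omega_{n}")
    for tag, err in (("1", model.error_plasma), ("2", model.error_urine)):
        if err["model"] == "combined":
            vec += [math.log(err["a"]), math.log(err["b"])]
            labels += [f"a{tag}", f"b{tag}"]
        else:
            key = "a" if err["model"] in ("additive", "exponential") else "b"
            vec.append(math.log(err[key]))
            labels.append(f"{key}{tag}")
    return np.array(vec), labels


def _pvec_unpack(model: PopulationModel, fitdata: FitData, vec: np.ndarray):
    names = model.param_names()
    gamma = {}
    i = 0
    for n in names:
        nb = len(model.betas_for(n))
        gamma[n] = np.array(vec[i:i + 1 + nb])
        i += 1 + nb
    omega = {}
    for n in names:
        omega[n] = math.exp(vec[i])
        i += 1
    err_p = dict(model.error_plasma)
    err_u = dict(model.error_urine)
    for err in (err_p, err_u):
        if err["model"] == "combined":
            err["a"], err["b"] = math.exp(vec[i]), math.exp(vec[i + 1])
            i += 2
        else:
            key = "a" if err["model"] in ("additive", "exponential") else "b"
            err[key] = math.exp(vec[i])
            i += 1
    return gamma, omega, err_p, err_u


def fisher_information(fitdata: FitData, model: PopulationModel,
                       fit: FitResult) -> dict:
    """Linearised Fisher information: RSEs, SEs and condition number kappa.

    The model is linearised around the conditional means of the random
    effects (FOCE-style); subject scores of the resulting Gaussian marginal
    likelihood are accumulated into a BHHH information matrix. kappa is the
    ratio of extreme eigenvalues of the correlation matrix of the estimates.
    Results are stored on ``fit`` and returned as a dict.
    """
    names = model.param_names()
    P = len(names)
    eta_hat = fit.etas
    pvec, labels = _pvec_pack(model, fitdata)

    def subject_moments(vec):
        """Per-subject marginal mean and covariance of the linearized model."""
        gamma, omega, err_p, err_u = _pvec_unpack(model, fitdata, vec)
        work = _model_from_gamma(model, gamma,
                                 {n: omega[n] ** 2 for n in names}, err_p, err_u)
        mu = _mu_matrix(work, fitdata, gamma)
        phi0 = mu + eta_hat
        f0p, f0u = fitdata.predict(work, _phi_to_psi(work, phi0))
        Jp = np.empty((fitdata.n_plasma, P))
        Ju = np.empty((fitdata.n_urine, P))
        h = 1e-4
        for j in range(P):
            phi = phi0.copy()
            phi[:, j] += h
            fp, fu = fitdata.predict(work, _phi_to_psi(work, phi))
            Jp[:, j] = (fp - f0p) / h
            Ju[:, j] = (fu - f0u) / h
        gp = _error_sd(err_p, f0p)
        gu = _error_sd(err_u, np.maximum(f0u, 1e-8))
        om2 = np.array([omega[n] ** 2 for n in names])
        means, covs = [], []
        for i in range(fitdata.n_sub):
            mp = fitdata.p_sub == i
            mun = fitdata.u_sub == i
            J = np.vstack([Jp[mp], Ju[mun]])
            m = np.concatenate([f0p[mp], f0u[mun]]) - J @ eta_hat[i]
            g2 = np.concatenate([gp[mp] ** 2, gu[mun] ** 2])
            means.append(m)
            covs.append((J * om2) @ J.T + np.diag(g2))
        return means, covs

    # expected Fisher information of the Gaussian marginal:
    #   F_jk = dm_j' S^-1 dm_k + 1/2 tr(S^-1 dS_j S^-1 dS_k)
    # with moment derivatives by central finite differences
    n_par = len(pvec)
    h = 1e-4 * np.maximum(np.abs(pvec), 1.0)
    m0, S0 = subject_moments(pvec)
    dm = [[None] * n_par for _ in range(fitdata.n_sub)]
    dS = [[None] * n_par for _ in range(fitdata.n_sub)]
    for j in range(n_par):
        up, dn = pvec.copy(), pvec.copy()
        up[j] += h[j]
        dn[j] -= h[j]
        m_up, S_up = subject_moments(up)
        m_dn, S_dn = subject_moments(dn)
        for i in range(fitdata.n_sub):
            dm[i][j] = (m_up[i] - m_dn[i]) / (2 * h[j])
            dS[i][j] = (S_up[i] - S_dn[i]) / (2 * h[j])
    fim = np.zeros((n_par, n_par))
    for i in range(fitdata.n_sub):
        if len(m0[i]) == 0:
            continue
        Sinv = np.linalg.inv(S0[i])
        b = [Sinv @ dm[i][j] for j in range(n_par)]
        A = [Sinv @ dS[i][j] for j in range(n_par)]
        for j in range(n_par):
            for k in range(j, n_par):
                v = dm[i][j] @ b[k] + 0.5 * np.sum(A[j] * A[k].T)
                fim[j, k] += v
                if k != j:
                    fim[k, j] += v
    try:
        cov = np.linalg.inv(fim)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        d = np.sqrt(diag)
        corr = cov / np.outer(d, d)
        ev = np.linalg.eigvalsh(corr)
        kappa = float(ev[-1] / max(ev[0], 1e-300)) if ev[0] > 0 else float("inf")
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
        d = np.full(n_par, np.nan)
        kappa = float("inf")

    se, rse = {}, {}
    i = 0
    for n in names:
        th = model.theta[n]
        if model.transform(n) == "logit":
            se_nat = th * (1 - th) * d[i]
        else:
            se_nat = th * d[i]
        se[f"theta_{n}"] = float(se_nat)
        rse[f"theta_{n}"] = float(100.0 * se_nat / abs(th))
        i += 1
        for rel, b in model.betas_for(n):
            se[f"beta_{n}_{rel.covariate}"] = float(d[i])
            rse[f"beta_{n}_{rel.covariate}"] = float(100.0 * d[i] / abs(b)) if b else float("inf")
            i += 1
    for n in names:
        om = model.omega[n]
        se[f"omega_{n}"] = float(om * d[i])
        rse[f"omega_{n}"] = float(100.0 * d[i])
        i += 1
    for tag, err in (("1", model.error_plasma), ("2", model.error_urine)):
        keys = ("a", "b") if err["model"] == "combined" else (
            ("a",) if err["model"] in ("additive", "exponential") else ("b",))
        for key in keys:
            se[f"{key}{tag}"] = float(err[key] * d[i])
            rse[f"{key}{tag}"] = float(100.0 * d[i])
            i += 1

    fit.se, fit.rse, fit.kappa = se, rse, kappa
    fit.covariance = cov
    fit.pvec_names = labels
    return {"se": se, "rse": rse, "kappa": kappa}


def shrinkage(fit: FitResult) -> dict[str, float]:
    """Conditional-distribution shrinkage, % per random effect."""
    return dict(fit.shrinkage)


def wald_test(beta_estimate: float, beta_se: float) -> float:
    """Two-sided normal p-value for beta = 0."""
    if beta_se <= 0:
        raise ValueError("standard error must be positive")
    z = abs(beta_estimate) / beta_se
    return float(2.0 * stats.norm.sf(z))


def shapiro_wilk_check(values) -> tuple[float, float]:
    """Shapiro-Wilk normality statistic and p-value (n >= 3, non-constant)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    stat, p = stats.shapiro(x)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Forward simulation on a fixed design (shared by diagnostics / trial / VPC)
# ---------------------------------------------------------------------------

def simulate_observations(model: PopulationModel, fitdata: FitData,
                          rng: np.random.Generator,
                          include_bsv: bool = True,
                          include_residual: bool = True):
    """Simulate one replicate of the dataset's design under ``model``.

    Returns (plasma values, urine values, eta, n_truncated): predictions on
    the observed design with fresh between-subject variability and residual
    errors; negative simulated concentrations are truncated at zero and
    counted.
    """
    names = model.param_names()
    om = np.array([model.omega[n] for n in names])
    eta = (rng.standard_normal((fitdata.n_sub, len(names))) * om
           if include_bsv else np.zeros((fitdata.n_sub, len(names))))
    psi = _natural_psi(model, fitdata, eta)
    fp, fu = fitdata.predict(model, psi)
    n_trunc = 0
    if include_residual:
        if model.error_plasma["model"] == "exponential":
            fp = fp * np.exp(model.error_plasma["a"] * rng.standard_normal(fitdata.n_plasma))
        else:
            fp = fp + _error_sd(model.error_plasma, fp) * rng.standard_normal(fitdata.n_plasma)
        if model.error_urine["model"] == "exponential":
            fu = fu * np.exp(model.error_urine["a"] * rng.standard_normal(fitdata.n_urine))
        else:
            fu = fu + _error_sd(model.error_urine, fu) * rng.standard_normal(fitdata.n_urine)
        n_trunc = int((fp < 0).sum() + (fu < 0).sum())
        fp = np.maximum(fp, 0.0)
        fu = np.maximum(fu, 0.0)
    return fp, fu, eta, n_trunc
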