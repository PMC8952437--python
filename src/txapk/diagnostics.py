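"""Simulation-based model validation: VPC, NPDE and bootstrap.

All diagnostics consume only the simulation interface of the population
model (simulate a replicate of the observed design) and are deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy import stats

from .data import PKDataset
from .saem import (FitData, FitResult, PopulationModel, SaemSettings,
                   saem_fit, shapiro_wilk_check, simulate_observations)

__all__ = ["VPCResult", "NPDEResult", "BootstrapResult", "vpc", "npde", "bootstrap"]

PCTS = (10.0, 50.0, 90.0)


@dataclass
class VPCResult:
    bin_times: np.ndarray
    observed: np.ndarray       # (3, n_bins) observed 10/50/90th percentiles
    band_lo: np.ndarray        # (3, n_bins) 2.5% prediction limit per percentile
    band_med: np.ndarray
    band_hi: np.ndarray
    n_simulations: int

    def coverage(self) -> float:
        """Fraction of (percentile, bin) cells whose observed value lies
        inside its simulated prediction band."""
        inside = (self.observed >= self.band_lo) & (self.observed <= self.band_hi)
        return float(inside.mean())


@dataclass
class NPDEResult:
    npde_plasma: np.ndarray
    npde_urine: np.ndarray
    shapiro_plasma: tuple[float, float]
    shapiro_urine: tuple[float, float]
    outside90_plasma: float
    outside90_urine: float

    @property
    def npde(self) -> np.ndarray:
        return np.concatenate([self.npde_plasma, self.npde_urine])


@dataclass
class BootstrapResult:
    table: dict                      # name -> (median, q1, q3)
    n_requested: int
    n_converged: int
    n_failed: int
    estimates: dict = field(default_factory=dict)  # name -> replicate values

    def contains(self, name: str, value: float) -> bool:
        _, q1, q3 = self.table[name]
        return q1 <= value <= q3


def _assign_bins(times: np.ndarray, nominal: np.ndarray, jitter: float = 10.0):
    """Bin observation times to the nearest nominal time when within the
    design's sampling window, otherwise fall back to quantile bins."""
    d = np.abs(times[:, None] - nominal[None, :])
    idx = d.argmin(axis=1)
    if np.all(d.min(axis=1) <= jitter + 1e-9):
        return idx, nominal
    n_bins = len(nominal)
    edges = np.quantile(times, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, n_bins - 1)
    centers = np.array([times[idx == b].mean() for b in range(n_bins)])
    return idx, centers


def vpc(dataset, model: PopulationModel, n_sim: int = 500, seed: int = 0,
        nominal_times=(15.0, 30.0, 60.0, 120.0, 180.0, 360.0)) -> VPCResult:
    """Visual predictive check on the plasma observations.

    Simulates ``n_sim`` replicate trials on the observed design (same doses,
    times and covariates) and compares the observed 10/50/90th percentiles
    per time bin with the prediction interval of each percentile across
    replicates.
    """
    if n_sim < 100:
        warnings.warn("VPC with fewer than 100 simulations is unreliable")
    fitdata = dataset if isinstance(dataset, FitData) else FitData(dataset)
    rng = np.random.default_rng(seed)
    times = np.array([o.time for o in fitdata.dataset.observations if o.kind == "plasma"])
    y = fitdata.y_plasma
    bins, centers = _assign_bins(times, np.asarray(nominal_times, dtype=float))
    n_bins = len(centers)

    def percentiles(values):
        out = np.empty((3, n_bins))
        for b in range(n_bins):
            sel = values[bins == b]
            out[:, b] = np.percentile(sel, PCTS) if len(sel) else np.nan
        return out

    observed = percentiles(y)
    sims = np.empty((n_sim, 3, n_bins))
    for s in range(n_sim):
        fp, _, _, _ = simulate_observations(model, fitdata, rng)
        sims[s] = percentiles(fp)
    return VPCResult(
        bin_times=centers,
        observed=observed,
        band_lo=np.percentile(sims, 2.5, axis=0),
        band_med=np.percentile(sims, 50.0, axis=0),
        band_hi=np.percentile(sims, 97.5, axis=0),
        n_simulations=n_sim,
    )


def npde(dataset, model: PopulationModel, n_sim: int = 500,
         seed: int = 0) -> NPDEResult:
    """Normalized prediction distribution errors.

    Per subject, the joint observation vector (plasma + urine) is
    decorrelated with the Cholesky factor of the empirical covariance of the
    simulated replicates; prediction discrepancies are rank-transformed
    through the standard-normal quantile function. Under the true model the
    NPDE are approximately N(0, 1).
    """
    fitdata = dataset if isinstance(dataset, FitData) else FitData(dataset)
    rng = np.random.default_rng(seed)
    K = n_sim
    sims_p = np.empty((K, fitdata.n_plasma))
    sims_u = np.empty((K, fitdata.n_urine))
    for k in range(K):
        fp, fu, _, _ = simulate_observations(model, fitdata, rng)
        sims_p[k] = fp
        sims_u[k] = fu

    npde_p = np.empty(fitdata.n_plasma)
    npde_u = np.empty(fitdata.n_urine)
    for i in range(fitdata.n_sub):
        mp = fitdata.p_sub == i
        mu_ = fitdata.u_sub == i
        yobs = np.concatenate([fitdata.y_plasma[mp], fitdata.y_urine[mu_]])
        sims = np.concatenate([sims_p[:, mp], sims_u[:, mu_]], axis=1)
        ni = sims.shape[1]
        if ni == 0:
            continue
        m = sims.mean(axis=0)
        if ni == 1:
            dec_obs = yobs - m
            dec_sim = sims - m
        else:
            V = np.cov(sims, rowvar=False)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                warnings.warn("singular simulation covariance; ridge-stabilised")
                L = np.linalg.cholesky(V + 1e-8 * np.eye(ni) * max(V.max(), 1.0))
            dec_obs = np.linalg.solve(L, yobs - m)
            dec_sim = np.linalg.solve(L, (sims - m).T).T
        ranks = (dec_sim < dec_obs).sum(axis=0)
        u = (ranks + 0.5) / (K + 1.0)
        z = stats.norm.ppf(u)
        npde_p[mp] = z[: mp.sum()]
        npde_u[mu_] = z[mp.sum():]

    crit = stats.norm.ppf(0.95)

    def _sw(x):
        if len(x) < 3 or np.ptp(x) == 0:
            return (float("nan"), float("nan"))
        return shapiro_wilk_check(x)

    return NPDEResult(
        npde_plasma=npde_p,
        npde_urine=npde_u,
        shapiro_plasma=_sw(npde_p),
        shapiro_urine=_sw(npde_u),
        outside90_plasma=(float((np.abs(npde_p) > crit).mean())
                          if npde_p.size else float("nan")),
        outside90_urine=(float((np.abs(npde_u) > crit).mean())
                         if npde_u.size else float("nan")),
    )


def _flat_estimates(model: PopulationModel) -> dict[str, float]:
    out = {}
    for n in model.param_names():
        out[f"theta_{n}"] = model.theta[n]
        for rel, b in model.betas_for(n):
            out[f"beta_{n}_{rel.covariate}"] = b
    for n in model.param_names():
        out[f"omega_{n}"] = model.omega[n]
    for tag, err in (("1", model.error_plasma), ("2", model.error_urine)):
        for key in ("a", "b"):
            if key in err:
                out[f"{key}{tag}"] = err[key]
    return out


def bootstrap(dataset, model: PopulationModel, n_rep: int = 500, seed: int = 0,
              settings: SaemSettings | None = None) -> BootstrapResult:
    """Nonparametric bootstrap of the final model, stratified by dose arm.

    Subjects are resampled with replacement within each arm (preserving the
    arm sizes); the final covariate structure is refit to each replicate.
    Non-converged replicates are excluded and counted; more than 20%
    failures triggers a validity warning.
    """
    ds = dataset if isinstance(dataset, PKDataset) else dataset.dataset
    settings = settings or SaemSettings(n_explore=120, n_smooth=60, n_chains=2,
                                        compute_fim=False, compute_ll=False)
    rng = np.random.default_rng(seed)
    by_arm: dict[str, list] = {}
    for s in ds.subjects:
        by_arm.setdefault(s.arm, []).append(s)

    values: dict[str, list[float]] = {}
    n_failed = 0
    for rep in range(n_rep):
        subjects, doses, obs = [], [], []
        k = 0
        for arm, subs in by_arm.items():
            pick = rng.integers(0, len(subs), size=len(subs))
            for j in pick:
                src = subs[j]
                k += 1
                new_id = f"B{k:03d}"
                clone = replace(src, id=new_id)
                subjects.append(clone)
                for d in ds.doses:
                    if d.subject == src.id:
                        doses.append(replace(d, subject=new_id))
                for o in ds.observations:
                    if o.subject == src.id:
                        obs.append(replace(o, subject=new_id))
        try:
            boot_ds = PKDataset(subjects=subjects, doses=doses, observations=obs)
            rep_settings = replace(settings, seed=seed + 7919 * (rep + 1))
            fit = saem_fit(boot_ds, model, rep_settings)
            for name, v in _flat_estimates(fit.model).items():
                values.setdefault(name, []).append(v)
        except Exception:  # noqa: BLE001 - failures excluded and counted
            n_failed += 1

    n_ok = n_rep - n_failed
    if n_rep and n_failed > 0.2 * n_rep:
        warnings.warn(f"bootstrap validity: {n_failed}/{n_rep} replicates failed")
    table = {
        name: (float(np.median(v)), float(np.percentile(v, 25)),
               float(np.percentile(v, 75)))
        for name, v in values.items()
    }
    return BootstrapResult(table=table, n_requested=n_rep, n_converged=n_ok,
                           n_failed=n_failed,
                           estimates={k: np.asarray(v) for k, v in values.items()})
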