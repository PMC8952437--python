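"""Candidate compartmental models for intravenous tranexamic acid.

The drug is given as a short zero-order infusion into a central compartment
(V1) with up to two peripheral compartments. Elimination routes:

* ``elim_a``    — the urinary route, from the central compartment, measured
  through the cumulative urine compartment (first-order or Michaelis-Menten);
* ``elim_a_prime`` — an additional non-urinary first-order route from the
  central compartment;
* ``elim_b``    — a hypothetical route from the first peripheral compartment
  (e.g. loss in hemorrhagic uterine blood; first-order or Michaelis-Menten).

For fully first-order central elimination the model is parameterised by the
TOTAL central clearance CL and the urinary excretion fraction p_urine, so
that the urinary micro-rate is k_urine = p_urine * CL / V1 and p_urine is the
fraction of the dose ultimately recovered in urine. Linear specs are
evaluated in closed form (sums of exponentials, superposition over doses);
saturable specs fall back to stiff-safe numerical integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralSpec",
    "StructuralParams",
    "CovariateRelation",
    "ConcentrationProfile",
    "TABLE_SPECS",
    "predict_profile",
    "terminal_half_life",
    "typical_value",
    "batch_disposition",
]

_FO = "first_order"
_MM = "michaelis_menten"


@dataclass(frozen=True)
class StructuralSpec:
    """Compartment count and elimination topology of one candidate model."""

    n_compartments: int = 2
    elim_a: str = _FO
    elim_a_prime: str = "none"
    elim_b: str = "none"

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise ValueError("n_compartments must be 1, 2 or 3")
        if self.elim_a not in (_FO, _MM):
            raise ValueError("elim_a must be first_order or michaelis_menten")
        if self.elim_a_prime not in ("none", _FO):
            raise ValueError("elim_a_prime must be none or first_order")
        if self.elim_b not in ("none", _FO, _MM):
            raise ValueError("elim_b invalid")
        if self.elim_b != "none" and self.n_compartments < 2:
            raise ValueError("elim_b requires at least 2 compartments")
        if self.elim_a == _MM and self.elim_a_prime == _FO:
            raise ValueError("saturable urinary route not combined with elim_a_prime")

    @property
    def dual_elimination(self) -> bool:
        return self.elim_a_prime == _FO

    @property
    def is_linear(self) -> bool:
        return self.elim_a == _FO and self.elim_b != _MM

    def param_names(self) -> list[str]:
        names: list[str] = []
        if self.elim_a == _FO:
            names.append("CL")
        else:
            names += ["Vmax", "Km"]
        names.append("V1")
        if self.n_compartments >= 2:
            names += ["Q", "V2"]
        if self.n_compartments == 3:
            names += ["Q2", "V3"]
        if self.dual_elimination:
            names.append("p_urine")
        if self.elim_b == _FO:
            names.append("CLB")
        elif self.elim_b == _MM:
            names += ["VmaxB", "KmB"]
        return names

    def label(self) -> str:
        parts = [f"{self.n_compartments}cmt", f"elimA={self.elim_a}"]
        if self.elim_a_prime != "none":
            parts.append(f"elimA'={self.elim_a_prime}")
        if self.elim_b != "none":
            parts.append(f"elimB={self.elim_b}")
        return ", ".join(parts)


#: the ten topologies of the base-model search, in search order
TABLE_SPECS: list[StructuralSpec] = [
    StructuralSpec(1, _FO, "none", "none"),
    StructuralSpec(1, _FO, _FO, "none"),
    StructuralSpec(2, _MM, "none", "none"),
    StructuralSpec(2, _MM, "none", _FO),
    StructuralSpec(2, _MM, "none", _MM),
    StructuralSpec(2, _FO, "none", "none"),
    StructuralSpec(2, _FO, "none", _FO),
    StructuralSpec(2, _FO, "none", _MM),
    StructuralSpec(2, _FO, _FO, "none"),
    StructuralSpec(3, _FO, "none", "none"),
]


@dataclass
class StructuralParams:
    """Individual (or typical) parameter values, clearances in L/min, volumes in L."""

    CL: float = 0.0
    V1: float = 1.0
    Q: float = 0.0
    V2: float = 1.0
    Q2: float = 0.0
    V3: float = 1.0
    p_urine: float = 1.0
    Vmax: float = 0.0
    Km: float = 1.0
    CLB: float = 0.0
    VmaxB: float = 0.0
    KmB: float = 1.0

    def validate(self, spec: StructuralSpec) -> None:
        for name in spec.param_names():
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {name}")
            if name == "p_urine":
                if not 0.0 <= v <= 1.0:
                    raise ValueError("p_urine must lie in [0, 1]")
            elif v <= 0:
                raise ValueError(f"parameter {name} must be positive")

    @property
    def k_urine(self) -> float:
        return self.p_urine * self.CL / self.V1


@dataclass(frozen=True)
class CovariateRelation:
    """A covariate acting on the log of one structural parameter.

    ``linear`` adds beta * x to the log-parameter (the exponential relation
    used for renal clearance on CL); ``power`` adds beta * log(x / ref)
    (allometric body-weight scaling of V1, ref = 70 kg).
    """

    target: str
    covariate: str
    form: str = "linear"
    ref: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "power"):
            raise ValueError("form must be linear or power")
        if self.form == "power" and self.ref <= 0:
            raise ValueError("power form needs ref > 0")

    def design_value(self, x: float | np.ndarray) -> float | np.ndarray:
        if self.form == "linear":
            return x
        return np.log(np.asarray(x, dtype=float) / self.ref)

    def label(self) -> str:
        if self.form == "linear":
            return f"{self.covariate} -> {self.target}"
        return f"log({self.covariate}/{self.ref:g}) -> {self.target}"


@dataclass
class ConcentrationProfile:
    times: np.ndarray
    plasma: np.ndarray
    urine_cumulative_amount: np.ndarray


# ---------------------------------------------------------------------------
# Linear disposition: decay rates and central-compartment weights
# ---------------------------------------------------------------------------

def batch_disposition(spec: StructuralSpec, p: dict[str, np.ndarray]):
    """Decay rates ``a`` and central weights ``w`` for linear specs, batched.

    The central amount after a unit bolus is A1(t) = sum_j w_j exp(-a_j t)
    with sum_j w_j = 1. Input arrays share a leading subject axis.
    """
    if not spec.is_linear:
        raise ValueError("batch_disposition requires a linear spec")
    CL, V1 = p["CL"], p["V1"]
    k10 = CL / V1
    if spec.elim_b == _FO:
        return _general_linear_disposition(spec, p)
    if spec.n_compartments == 1:
        a = k10[..., None]
        w = np.ones_like(a)
        return a, w
    k12 = p["Q"] / V1
    k21 = p["Q"] / p["V2"]
    if spec.n_compartments == 2:
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        span = np.maximum(alpha - beta, 1e-300)
        w1 = (alpha - k21) / span
        w2 = (k21 - beta) / span
        a = np.stack([alpha, beta], axis=-1)
        w = np.stack([w1, w2], axis=-1)
        return a, w
    return _general_linear_disposition(spec, p)


def _general_linear_disposition(spec: StructuralSpec, p: dict[str, np.ndarray]):
    """Eigendecomposition path for 3-compartment and peripheral-elimination specs."""
    CL = np.atleast_1d(np.asarray(p["CL"], dtype=float))
    V1 = np.atleast_1d(np.asarray(p["V1"], dtype=float))
    n = CL.shape[0]
    nc = spec.n_compartments
    M = np.zeros((n, nc, nc))
    k10 = CL / V1
    M[:, 0, 0] -= k10
    if nc >= 2:
        k12 = np.atleast_1d(p["Q"]) / V1
        k21 = np.atleast_1d(p["Q"]) / np.atleast_1d(p["V2"])
        M[:, 0, 0] -= k12
        M[:, 0, 1] += k21
        M[:, 1, 0] += k12
        M[:, 1, 1] -= k21
        if spec.elim_b == _FO:
            M[:, 1, 1] -= np.atleast_1d(p["CLB"]) / np.atleast_1d(p["V2"])
    if nc == 3:
        k13 = np.atleast_1d(p["Q2"]) / V1
        k31 = np.atleast_1d(p["Q2"]) / np.atleast_1d(p["V3"])
        M[:, 0, 0] -= k13
        M[:, 0, 2] += k31
        M[:, 2, 0] += k13
        M[:, 2, 2] -= k31
    lam, vec = np.linalg.eig(M)
    vinv = np.linalg.inv(vec)
    w = (vec[:, 0, :] * vinv[:, :, 0]).real
    a = -lam.real
    a = np.maximum(a, 1e-300)
    return a, w


def _infusion_shape(a, dt, tau):
    """Central response to a unit-rate infusion: per-exponential shape factor.

    During the infusion (dt <= tau): (1 - exp(-a dt)) / a; afterwards the
    decayed end-of-infusion value. dt <= 0 contributes zero.
    """
    dt = np.maximum(dt, 0.0)
    t_on = np.minimum(dt, tau)
    t_off = np.maximum(dt - tau, 0.0)
    return np.exp(-a * t_off) * -np.expm1(-a * t_on) / a


def _infusion_shape_integral(a, dt, tau):
    """Time-integral of :func:`_infusion_shape` from 0 to dt (for cumulative urine)."""
    dt = np.maximum(dt, 0.0)
    t_on = np.minimum(dt, tau)
    t_off = np.maximum(dt - tau, 0.0)
    part_on = t_on / a + np.expm1(-a * t_on) / a**2
    e_on = -np.expm1(-a * t_on)
    part_off = e_on * -np.expm1(-a * t_off) / a**2
    return part_on + part_off


# ---------------------------------------------------------------------------
# Profile prediction
# ---------------------------------------------------------------------------

def predict_profile(
    spec: StructuralSpec,
    params: StructuralParams,
    doses,
    times,
    method: str = "auto",
    rtol: float = 1e-8,
) -> ConcentrationProfile:
    """Plasma concentration (mg/L) and cumulative urinary amount (mg).

    ``doses`` is a list of objects with ``time``, ``amount`` and
    ``infusion_duration`` attributes (e.g. :class:`txapk.data.DoseEvent`).
    Linear specs are evaluated in closed form by superposition; saturable
    specs (or ``method="ode"``) by numerical integration.
    """
    params.validate(spec)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if len(doses) == 0:
        z = np.zeros_like(times)
        return ConcentrationProfile(times, z, z.copy())
    if method == "auto":
        method = "closed_form" if spec.is_linear else "ode"
    if method == "closed_form":
        return _predict_linear(spec, params, doses, times)
    return _predict_ode(spec, params, doses, times, rtol=rtol)


def _predict_linear(spec, params, doses, times):
    p = {name: np.asarray([getattr(params, name)]) for name in
         ("CL", "V1", "Q", "V2", "Q2", "V3", "CLB")}
    a, w = batch_disposition(spec, p)
    a, w = a[0], w[0]
    pur = params.p_urine if spec.dual_elimination else 1.0
    ku = pur * params.CL / params.V1
    conc = np.zeros_like(times)
    au = np.zeros_like(times)
    for d in doses:
        dt = times - d.time
        rate = d.amount / d.infusion_duration
        shape = _infusion_shape(a[None, :], dt[:, None], d.infusion_duration)
        conc += rate / params.V1 * (w[None, :] * shape).sum(axis=1)
        integ = _infusion_shape_integral(a[None, :], dt[:, None], d.infusion_duration)
        au += ku * rate * (w[None, :] * integ).sum(axis=1)
    return ConcentrationProfile(times, conc, au)


def _predict_ode(spec, params, doses, times, rtol=1e-8):
    nc = spec.n_compartments
    k10 = params.CL / params.V1 if spec.elim_a == _FO else 0.0
    pur = params.p_urine if spec.dual_elimination else 1.0

    def rhs(t, y):
        A = y[:nc]
        dA = np.zeros(nc + 1)
        C1 = A[0] / params.V1
        rate_in = sum(
            d.amount / d.infusion_duration
            for d in doses
            if d.time <= t < d.time + d.infusion_duration
        )
        urinary = pur * k10 * A[0] if spec.elim_a == _FO else (
            params.Vmax * C1 / (params.Km + C1)
        )
        nonurinary = (1.0 - pur) * k10 * A[0]
        dA[0] = rate_in - urinary - nonurinary
        if nc >= 2:
            k12 = params.Q / params.V1
            k21 = params.Q / params.V2
            dA[0] += -k12 * A[0] + k21 * A[1]
            dA[1] = k12 * A[0] - k21 * A[1]
            C2 = A[1] / params.V2
            if spec.elim_b == _FO:
                dA[1] -= params.CLB / params.V2 * A[1]
            elif spec.elim_b == _MM:
                dA[1] -= params.VmaxB * C2 / (params.KmB + C2)
        if nc == 3:
            k13 = params.Q2 / params.V1
            k31 = params.Q2 / params.V3
            dA[0] += -k13 * A[0] + k31 * A[2]
            dA[2] = k13 * A[0] - k31 * A[2]
        dA[nc] = urinary
        return dA

    t_end = float(max(times[-1], max(d.time + d.infusion_duration for d in doses)))
    breakpoints = sorted(
        {d.time for d in doses} | {d.time + d.infusion_duration for d in doses}
    )
    sol = solve_ivp(
        rhs, (0.0, t_end + 1e-9), np.zeros(nc + 1), t_eval=times,
        method="LSODA", rtol=rtol, atol=1e-10, max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return ConcentrationProfile(times, sol.y[0] / params.V1, sol.y[nc])


def terminal_half_life(params: StructuralParams, spec: StructuralSpec) -> float:
    """Terminal-phase half-life ln(2)/lambda_z in minutes (linear specs only)."""
    if not spec.is_linear:
        raise ValueError("terminal half-life is defined for linear specs only")
    p = {name: np.asarray([getattr(params, name)]) for name in
         ("CL", "V1", "Q", "V2", "Q2", "V3", "CLB")}
    a, w = batch_disposition(spec, p)
    # discard exponential components that contribute negligibly to the
    # profile (e.g. a vanishing inter-compartmental clearance leaves a
    # zero-weight, arbitrarily slow eigenrate)
    mask = np.abs(w[0]) > 1e-6 * np.abs(w[0]).sum()
    lam_z = float(np.min(a[0][mask]))
    return np.log(2.0) / lam_z


def typical_value(
    theta: dict[str, float],
    betas: list[tuple[CovariateRelation, float]],
    covariates: dict[str, float],
) -> StructuralParams:
    """Typical structural parameters from fixed effects and covariate values.

    Each covariate relation acts on the log scale: exponential-linear for the
    ``linear`` form (psi = theta * exp(beta x)) and normalised power for the
    ``power`` form (psi = theta * (x / ref)^beta). With beta = 0, or a power
    covariate at its reference value, the typical value equals theta.
    """
    values = dict(theta)
    for rel, beta in betas:
        if rel.covariate not in covariates:
            raise KeyError(f"missing reference covariate {rel.covariate}")
        x = rel.design_value(covariates[rel.covariate])
        values[rel.target] = values[rel.target] * float(np.exp(beta * x))
    return StructuralParams(**values)
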