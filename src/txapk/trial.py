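"""Synthetic two-arm cesarean-hemorrhage PK trials.

Generates virtual parturient cohorts under the reference trial design: two
randomised arms (0.5 g, n = 34; 1 g, n = 45) of a 1-minute intravenous
tranexamic-acid bolus at T0, plasma samples at 15/30/60/120/180/360 min with
a +/- 10 min window, two urine collections within 6 h, and ~10% rescue
second doses (median 87 min). Covariates are drawn from truncated normals
at the reference per-arm means/SDs, and observations are simulated from the
reference final covariate model (its estimates are the generative defaults),
so that every downstream stage — estimation, covariate selection,
diagnostics, dose simulation — can be scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import DoseEvent, Observation, PKDataset, SubjectRecord
from .saem import FitData, PopulationModel, simulate_observations
from .structural import CovariateRelation, StructuralSpec

__all__ = [
    "ARM_COVARIATES",
    "REFERENCE_ESTIMATES",
    "REFERENCE_RSE",
    "TrialDesign",
    "GenerativeTruth",
    "final_model",
    "base_model",
    "sample_covariates",
    "generate_trial",
]

#: per-arm covariate moments (mean, SD) of the recruited parturients;
#: serum creatinine in mg/L, weights kg, height cm, bleeding volume mL
ARM_COVARIATES = {
    "TXA0.5g": {
        "n": 34,
        "age": (34.0, 5.0),
        "height": (166.0, 8.0),
        "bw_before": (73.2, 21.1),
        "serum_creatinine": (6.5, 1.5),
        "bleeding_volume": (1091.0, 273.0),
        "dose_mg": 500.0,
    },
    "TXA1g": {
        "n": 45,
        "age": (33.0, 4.0),
        "height": (164.0, 7.0),
        "bw_before": (72.0, 17.0),
        "serum_creatinine": (6.7, 1.6),
        "bleeding_volume": (1163.0, 318.0),
        "dose_mg": 1000.0,
    },
}

#: published final-model population estimates (clearances L/min, volumes L;
#: omegas are SDs of the random effects; a1 mg/L)
REFERENCE_ESTIMATES = {
    "theta_CL": 0.077,
    "beta_CL": 0.0039,
    "theta_V1": 9.25,
    "beta_V1": 1.41,
    "theta_Q": 0.32,
    "theta_V2": 9.49,
    "theta_p_urine": 0.54,
    "omega_CL": 0.20,
    "omega_V1": 0.59,
    "omega_Q": 0.67,
    "omega_V2": 0.13,
    "omega_p_urine": 0.46,
    "a1": 0.44,
    "b1": 0.15,
    "b2": 0.52,
}

#: published relative standard errors (%) of the final-model estimates
REFERENCE_RSE = {
    "theta_CL": 7.3,
    "beta_CL": 11.8,
    "theta_V1": 12.0,
    "beta_V1": 25.8,
    "theta_Q": 15.3,
    "theta_V2": 5.1,
    "theta_p_urine": 7.0,
    "omega_CL": 11.2,
    "omega_V1": 14.1,
    "omega_Q": 18.8,
    "omega_V2": 31.9,
    "omega_p_urine": 11.9,
    "a1": 33.0,
    "b1": 6.8,
    "b2": 7.9,
}

DUAL_2CMT = StructuralSpec(2, "first_order", "first_order", "none")

#: final covariate structure: renal clearance on CL (exponential-linear),
#: pre-pregnancy body weight on V1 (allometric power, 70 kg reference)
FINAL_RELATIONS = [
    CovariateRelation("CL", "ECLCR_bef", "linear"),
    CovariateRelation("V1", "BWBEF", "power", ref=70.0),
]


def final_model(p_urine_transform: str = "logit") -> PopulationModel:
    """The published final covariate model as a fully specified PopulationModel."""
    r = REFERENCE_ESTIMATES
    return PopulationModel(
        spec=DUAL_2CMT,
        theta={
            "CL": r["theta_CL"], "V1": r["theta_V1"], "Q": r["theta_Q"],
            "V2": r["theta_V2"], "p_urine": r["theta_p_urine"],
        },
        betas=[(FINAL_RELATIONS[0], r["beta_CL"]), (FINAL_RELATIONS[1], r["beta_V1"])],
        omega={
            "CL": r["omega_CL"], "V1": r["omega_V1"], "Q": r["omega_Q"],
            "V2": r["omega_V2"], "p_urine": r["omega_p_urine"],
        },
        error_plasma={"model": "combined", "a": r["a1"], "b": r["b1"]},
        error_urine={"model": "proportional", "b": r["b2"]},
        p_urine_transform=p_urine_transform,
    )


def base_model(omega: dict | None = None) -> PopulationModel:
    """The covariate-free base model (its published structural estimates).

    The base-model report prints no between-subject variabilities, so the
    omegas must be supplied by the caller; defaults fall back to the final
    model's values.
    """
    om = omega or {
        "CL": 0.20, "V1": 0.59, "Q": 0.67, "V2": 0.13, "p_urine": 0.46,
    }
    return PopulationModel(
        spec=DUAL_2CMT,
        theta={"CL": 0.14, "V1": 17.66, "Q": 0.079, "V2": 8.12, "p_urine": 0.61},
        betas=[],
        omega=om,
        error_plasma={"model": "combined", "a": 0.44, "b": 0.15},
        error_urine={"model": "proportional", "b": 0.52},
    )


@dataclass
class TrialDesign:
    """Sampling design of the synthetic trial."""

    n_per_arm: dict[str, int] = field(
        default_factory=lambda: {"TXA0.5g": 34, "TXA1g": 45})
    nominal_times: tuple = (15.0, 30.0, 60.0, 120.0, 180.0, 360.0)
    time_jitter: float = 10.0
    urine_intervals: tuple = ((0.0, 180.0), (180.0, 360.0))
    urine_volume_median: float = 0.4   # L, log-normal
    urine_volume_sdlog: float = 0.4
    rescue_probability: float = 8.0 / 79.0
    rescue_time_median: float = 87.0   # min, log-normal
    rescue_time_sdlog: float = 0.5
    infusion_duration: float = 1.0


@dataclass
class GenerativeTruth:
    """The model and covariate distributions used to simulate a trial."""

    model: PopulationModel = field(default_factory=final_model)
    arm_covariates: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in ARM_COVARIATES.items()})


def _trunc_normal(rng, mean, sd, lo, hi=np.inf, size=1):
    """Truncated normal whose location is adjusted so the truncated mean
    matches the requested mean (fixed-point correction for the truncation
    bias, a few iterations suffice)."""
    loc = mean
    for _ in range(4):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        loc += mean - stats.truncnorm.mean(a, b, loc=loc, scale=sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def sample_covariates(n: int, seed_or_rng, arm: str = "TXA1g",
                      truth: GenerativeTruth | None = None,
                      id_prefix: str = "S") -> list[SubjectRecord]:
    """Draw n virtual parturients from one arm's covariate distributions.

    Age, height and pre-pregnancy weight are truncated normals at the arm's
    published moments; the weight at caesarean adds an independent truncated
    pregnancy gain (mean 11 kg, SD 4 kg); bleeding volume is truncated at the
    800 mL inclusion criterion.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    truth = truth or GenerativeTruth()
    mom = truth.arm_covariates[arm]
    age = _trunc_normal(rng, *mom["age"], lo=18.0, hi=50.0, size=n)
    height = _trunc_normal(rng, *mom["height"], lo=140.0, hi=200.0, size=n)
    bwbef = _trunc_normal(rng, *mom["bw_before"], lo=40.0, size=n)
    gain = _trunc_normal(rng, 11.0, 4.0, lo=0.0, size=n)
    scr = _trunc_normal(rng, *mom["serum_creatinine"], lo=2.5, size=n)
    bleed = _trunc_normal(rng, *mom["bleeding_volume"], lo=800.0, size=n)
    return [
        SubjectRecord(
            id=f"{id_prefix}{i + 1:03d}",
            age=float(age[i]), height=float(height[i]),
            bw_before=float(bwbef[i]), bw=float(bwbef[i] + gain[i]),
            serum_creatinine=float(scr[i]), arm=arm,
            bleeding_volume=float(bleed[i]),
        )
        for i in range(n)
    ]


def generate_trial(design: TrialDesign | None = None,
                   truth: GenerativeTruth | None = None,
                   seed: int = 0) -> tuple[PKDataset, dict]:
    """Simulate a complete synthetic trial.

    Returns the dataset and a truth ledger with the hidden individual
    parameters (for recovery scoring), the sampled etas, and the count of
    noise values truncated at zero.
    """
    design = design or TrialDesign()
    truth = truth or GenerativeTruth()
    rng = np.random.default_rng(seed)

    subjects: list[SubjectRecord] = []
    counter = 1
    for arm, n in design.n_per_arm.items():
        subs = sample_covariates(n, rng, arm=arm, truth=truth,
                                 id_prefix="S")
        for s in subs:
            s.id = f"S{counter:03d}"
            counter += 1
        subjects.extend(subs)

    doses: list[DoseEvent] = []
    obs_skeleton: list[Observation] = []
    for s in subjects:
        amount = truth.arm_covariates[s.arm]["dose_mg"]
        doses.append(DoseEvent(subject=s.id, time=0.0, amount=amount,
                               infusion_duration=design.infusion_duration))
        if rng.uniform() < design.rescue_probability:
            t_rescue = float(np.exp(
                np.log(design.rescue_time_median)
                + design.rescue_time_sdlog * rng.standard_normal()))
            t_rescue = min(max(t_rescue, 15.0), 300.0)
            doses.append(DoseEvent(subject=s.id, time=t_rescue, amount=amount,
                                   infusion_duration=design.infusion_duration))
        times = np.array(design.nominal_times) + rng.uniform(
            -design.time_jitter, design.time_jitter, size=len(design.nominal_times))
        times = np.sort(np.maximum(times, design.infusion_duration + 1.0))
        for t in times:
            obs_skeleton.append(Observation(subject=s.id, time=float(t), value=0.0))
        for (t0, t1) in design.urine_intervals:
            vol = float(np.exp(np.log(design.urine_volume_median)
                               + design.urine_volume_sdlog * rng.standard_normal()))
            obs_skeleton.append(Observation(
                subject=s.id, time=t1, value=0.0, kind="urine",
                interval_start=t0, urine_volume=vol))

    skeleton = PKDataset(subjects=subjects, doses=doses, observations=obs_skeleton)
    fitdata = FitData(skeleton)
    fp, fu, eta, n_trunc = simulate_observations(
        truth.model, fitdata, rng, include_bsv=True, include_residual=True)

    # write the simulated values back into a fresh validated dataset
    plasma = [o for o in skeleton.observations if o.kind == "plasma"]
    urine = [o for o in skeleton.observations if o.kind == "urine"]
    new_obs = []
    for o, v in zip(plasma, fp):
        new_obs.append(Observation(subject=o.subject, time=o.time, value=float(v)))
    for o, v in zip(urine, fu):
        new_obs.append(Observation(subject=o.subject, time=o.time, value=float(v),
                                   kind="urine", interval_start=o.interval_start,
                                   urine_volume=o.urine_volume))
    dataset = PKDataset(subjects=subjects, doses=doses, observations=new_obs)

    from .saem import _natural_psi  # hidden individual parameters
    psi = _natural_psi(truth.model, fitdata, eta)
    ledger = {
        "model": truth.model,
        "eta": {fitdata.ids[i]: eta[i] for i in range(fitdata.n_sub)},
        "psi": {name: {fitdata.ids[i]: float(v[i]) for i in range(fitdata.n_sub)}
                for name, v in psi.items()},
        "n_truncated": n_trunc,
        "seed": seed,
    }
    return dataset, ledger
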