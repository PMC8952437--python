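"""Event-record data model for the tranexamic-acid population-PK analysis.

One row per dose or observation, NONMEM-style long format. Times are minutes
from the first dose (T0), plasma concentrations in mg/L, urine observations
are interval concentrations (amount collected over (interval_start, time]
divided by the collected volume in litres). Serum creatinine is stored in
mg/L (the clinically reported values, ~6.5 mg/L, i.e. 0.65 mg/dL) and
converted to mg/dL inside the renal-function formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectRecord",
    "DoseEvent",
    "Observation",
    "PKDataset",
    "CovariatePanel",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "derive_covariates",
    "covariate_table",
    "compare_baseline",
]

CSV_COLUMNS = [
    "ID", "TIME", "DV", "DVID", "AMT", "TINF", "USTART", "UVOL",
    "AGE", "HT", "BWBEF", "BW", "SCR", "ARM", "BLEED",
]


class SchemaError(ValueError):
    """Input file does not declare the required event-record columns."""


class ValidationError(ValueError):
    """Dataset violates an event-record invariant."""


@dataclass
class SubjectRecord:
    """Baseline record for one parturient.

    Weights in kg, height in cm, serum creatinine in mg/L, bleeding volume
    in mL. ``arm`` is the randomised dose group label.
    """

    id: str
    age: float
    height: float
    bw_before: float
    bw: float
    serum_creatinine: float
    arm: str = "TXA1g"
    bleeding_volume: float = 1000.0
    weight_loss_flag: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.age > 0 and self.height > 0 and self.serum_creatinine > 0):
            raise ValidationError(
                f"subject {self.id}: age, height and serum creatinine must be positive"
            )
        if self.bw_before <= 0 or self.bw <= 0:
            raise ValidationError(f"subject {self.id}: weights must be positive")
        if self.bw < self.bw_before:
            # weight loss during pregnancy is anomalous but tolerated when flagged
            if not self.weight_loss_flag:
                raise ValidationError(
                    f"subject {self.id}: bw < bw_before without explicit weight_loss_flag"
                )
        if self.bleeding_volume < 800:
            raise ValidationError(
                f"subject {self.id}: bleeding volume {self.bleeding_volume} below the "
                "800 mL inclusion criterion"
            )


@dataclass
class DoseEvent:
    """Intravenous dose: ``amount`` mg given over ``infusion_duration`` min."""

    subject: str
    time: float
    amount: float
    infusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValidationError(f"subject {self.subject}: non-positive dose amount")
        if self.infusion_duration <= 0:
            raise ValidationError(
                f"subject {self.subject}: infusion duration must be positive"
            )


@dataclass
class Observation:
    """A plasma concentration or a urine interval concentration (mg/L)."""

    subject: str
    time: float
    value: float
    kind: str = "plasma"  # {"plasma", "urine"}
    interval_start: float | None = None
    urine_volume: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("plasma", "urine"):
            raise ValidationError(f"unknown observation kind {self.kind!r}")
        if self.value < 0:
            raise ValidationError(
                f"subject {self.subject}: negative observation at t={self.time}"
            )
        if self.kind == "urine":
            if self.interval_start is None or self.urine_volume is None:
                raise ValidationError(
                    f"subject {self.subject}: urine observation requires interval fields"
                )
            if not self.interval_start < self.time:
                raise ValidationError(
                    f"subject {self.subject}: urine interval_start must precede time"
                )
            if self.urine_volume <= 0:
                raise ValidationError(
                    f"subject {self.subject}: urine volume must be positive"
                )
        else:
            if self.interval_start is not None or self.urine_volume is not None:
                raise ValidationError(
                    f"subject {self.subject}: plasma observation carries urine fields"
                )


@dataclass
class PKDataset:
    """Validated event-record dataset: subjects, doses, observations."""

    subjects: list[SubjectRecord]
    doses: list[DoseEvent]
    observations: list[Observation]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "PKDataset":
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids")
        known = set(ids)
        for d in self.doses:
            if d.subject not in known:
                raise ValidationError(f"dose references unknown subject {d.subject}")
        for o in self.observations:
            if o.subject not in known:
                raise ValidationError(
                    f"observation references unknown subject {o.subject}"
                )
        self.doses.sort(key=lambda d: (d.subject, d.time))
        self.observations.sort(key=lambda o: (o.subject, o.time))
        first_dose: dict[str, float] = {}
        for d in self.doses:
            first_dose.setdefault(d.subject, d.time)
        for o in self.observations:
            if o.subject not in first_dose:
                raise ValidationError(f"subject {o.subject} has observations but no dose")
            if o.time < first_dose[o.subject]:
                raise ValidationError(
                    f"subject {o.subject}: observation at t={o.time} precedes first dose"
                )
        return self

    def subject_map(self) -> dict[str, SubjectRecord]:
        return {s.id: s for s in self.subjects}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def counts(self) -> dict[str, int]:
        n_pl = sum(o.kind == "plasma" for o in self.observations)
        n_ur = sum(o.kind == "urine" for o in self.observations)
        return {
            "subjects": self.n_subjects,
            "doses": len(self.doses),
            "plasma": n_pl,
            "urine": n_ur,
        }


# ---------------------------------------------------------------------------
# Covariate derivation
# ---------------------------------------------------------------------------

#: candidate covariate panel columns (weight-dependent measures computed with
#: the pre-pregnancy weight, suffix ``_bef``, and with the weight at caesarean)
PANEL_COLUMNS = [
    "AGE", "HT", "BWBEF", "BW", "IW",
    "BMI_bef", "BMI", "ABW_bef", "ABW", "LBW_bef", "LBW", "BSA_bef", "BSA",
    "ECLCR_bef", "ECLCR", "EGFR_CKDEPI_bef", "EGFR_CKDEPI",
    "EGFR_MDRD_bef", "EGFR_MDRD",
]


@dataclass
class CovariatePanel:
    """All derived covariates for one subject (a pure function of the record)."""

    subject: str
    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def bmi(weight: float, height_cm: float) -> float:
    return weight / (height_cm / 100.0) ** 2


def ideal_weight_female(height_cm: float) -> float:
    """Devine ideal body weight for women: 45.5 kg + 2.3 kg per inch over 5 ft."""
    inches = height_cm / 2.54
    return 45.5 + 2.3 * (inches - 60.0)


def adjusted_weight(weight: float, iw: float, factor: float = 0.4) -> float:
    return iw + factor * (weight - iw)


def lean_weight_female(weight: float, height_cm: float) -> float:
    """Janmahasatian fat-free mass for women."""
    return 9270.0 * weight / (8780.0 + 244.0 * bmi(weight, height_cm))


def bsa_dubois(weight: float, height_cm: float) -> float:
    return 0.007184 * weight**0.425 * height_cm**0.725


def cockcroft_gault_female(age: float, weight: float, scr_mg_l: float) -> float:
    """Estimated creatinine clearance (mL/min), female coefficient 0.85."""
    scr_mg_dl = scr_mg_l / 10.0
    return 0.85 * (140.0 - age) * weight / (72.0 * scr_mg_dl)


def ckdepi_2009_female(age: float, scr_mg_l: float) -> float:
    """CKD-EPI 2009 eGFR for women, mL/min/1.73 m^2."""
    scr = scr_mg_l / 10.0
    ratio = scr / 0.7
    return 144.0 * min(ratio, 1.0) ** -0.329 * max(ratio, 1.0) ** -1.209 * 0.993**age


def mdrd_female(age: float, scr_mg_l: float) -> float:
    """4-variable MDRD eGFR for women, mL/min/1.73 m^2."""
    scr = scr_mg_l / 10.0
    return 175.0 * scr**-1.154 * age**-0.203 * 0.742


def derive_covariates(subject: SubjectRecord) -> CovariatePanel:
    """Full candidate-covariate panel for one subject.

    Body-size measures are computed twice, with the pre-pregnancy weight and
    with the weight at caesarean. The eGFR formulas are weight-independent
    per 1.73 m^2; they are de-normalised by the subject's Du Bois BSA
    (eGFR * BSA / 1.73), which is what makes the "before" and "at caesarean"
    variants differ.
    """
    s = subject
    iw = ideal_weight_female(s.height)
    vals: dict[str, float] = {
        "AGE": s.age,
        "HT": s.height,
        "BWBEF": s.bw_before,
        "BW": s.bw,
        "IW": iw,
    }
    for suffix, w in (("_bef", s.bw_before), ("", s.bw)):
        sa = bsa_dubois(w, s.height)
        vals["BMI" + suffix] = bmi(w, s.height)
        vals["ABW" + suffix] = adjusted_weight(w, iw)
        vals["LBW" + suffix] = lean_weight_female(w, s.height)
        vals["BSA" + suffix] = sa
        vals["ECLCR" + suffix] = cockcroft_gault_female(s.age, w, s.serum_creatinine)
        vals["EGFR_CKDEPI" + suffix] = ckdepi_2009_female(s.age, s.serum_creatinine) * sa / 1.73
        vals["EGFR_MDRD" + suffix] = mdrd_female(s.age, s.serum_creatinine) * sa / 1.73
    for k, v in vals.items():
        if not (math.isfinite(v) and v > 0):
            raise ValidationError(f"subject {s.id}: derived covariate {k} = {v}")
    return CovariatePanel(subject=s.id, values=vals)


def covariate_table(dataset: PKDataset) -> pd.DataFrame:
    """Panel for every subject as a DataFrame indexed by subject id."""
    rows = {s.id: derive_covariates(s).values for s in dataset.subjects}
    return pd.DataFrame.from_dict(rows, orient="index")[PANEL_COLUMNS]


# ---------------------------------------------------------------------------
# Baseline group comparison
# ---------------------------------------------------------------------------

def compare_baseline(group_a, group_b, variable: str) -> dict:
    """Compare a baseline covariate between the two dose arms.

    Variance homogeneity is checked with Levene's test (alpha = 5%); if met,
    an independent-samples t-test is used, otherwise a Kruskal-Wallis test.
    Returns the chosen test, its statistic and p-value.
    """
    def _values(group):
        if len(group) and isinstance(next(iter(group)), SubjectRecord):
            return np.asarray([derive_covariates(s)[variable] for s in group], dtype=float)
        return np.asarray(group, dtype=float)

    xa = _values(group_a)
    xb = _values(group_b)
    if len(xa) < 2 or len(xb) < 2:
        raise ValidationError("need at least 2 subjects per group")
    if xa.std() == 0 and xb.std() == 0:
        raise ValidationError(f"zero variance in both groups for {variable}")
    lev_stat, lev_p = stats.levene(xa, xb)
    if lev_p > 0.05:
        stat, p = stats.ttest_ind(xa, xb)
        test = "t-test"
        if np.isnan(p):  # identical constant groups
            stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(xa, xb)
        test = "kruskal-wallis"
    return {
        "variable": variable,
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "levene_p": float(lev_p),
        "mean_a": float(xa.mean()),
        "mean_b": float(xb.mean()),
    }


# ---------------------------------------------------------------------------
# Event-record CSV I/O
# ---------------------------------------------------------------------------

def read_dataset(path) -> PKDataset:
    """Read a long-format event-record CSV into a validated :class:`PKDataset`.

    Rows with AMT > 0 are dose events; rows with a DV value are observations
    (DVID 1 = plasma, 2 = urine with USTART/UVOL interval fields). Baseline
    covariates are repeated on every row of a subject; the first row wins.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    subjects: list[SubjectRecord] = []
    seen: set[str] = set()
    doses: list[DoseEvent] = []
    obs: list[Observation] = []
    for _, row in df.iterrows():
        sid = str(row["ID"])
        if sid not in seen:
            seen.add(sid)
            bwbef, bw = float(row["BWBEF"]), float(row["BW"])
            subjects.append(
                SubjectRecord(
                    id=sid,
                    age=float(row["AGE"]),
                    height=float(row["HT"]),
                    bw_before=bwbef,
                    bw=bw,
                    serum_creatinine=float(row["SCR"]),
                    arm=str(row["ARM"]),
                    bleeding_volume=float(row["BLEED"]),
                    weight_loss_flag=bw < bwbef,
                )
            )
        amt = row["AMT"]
        if pd.notna(amt) and float(amt) > 0:
            doses.append(
                DoseEvent(
                    subject=sid,
                    time=float(row["TIME"]),
                    amount=float(amt),
                    infusion_duration=float(row["TINF"]),
                )
            )
        dv = row["DV"]
        if pd.notna(dv):
            dvid = int(row["DVID"])
            if dvid == 2:
                obs.append(
                    Observation(
                        subject=sid,
                        time=float(row["TIME"]),
                        value=float(dv),
                        kind="urine",
                        interval_start=float(row["USTART"]),
                        urine_volume=float(row["UVOL"]),
                    )
                )
            else:
                obs.append(
                    Observation(subject=sid, time=float(row["TIME"]), value=float(dv))
                )
    return PKDataset(subjects=subjects, doses=doses, observations=obs)


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a :class:`PKDataset` back to the event-record CSV dialect.

    Numeric fields are written with Python's shortest round-tripping float
    representation, so ``read_dataset(write_dataset(ds))`` reproduces every
    numeric field bit-exactly.
    """
    smap = dataset.subject_map()
    rows = []

    def base(sid: str) -> dict:
        s = smap[sid]
        return {
            "ID": sid, "AGE": s.age, "HT": s.height, "BWBEF": s.bw_before,
            "BW": s.bw, "SCR": s.serum_creatinine, "ARM": s.arm,
            "BLEED": s.bleeding_volume,
        }

    for d in dataset.doses:
        r = base(d.subject)
        r.update(TIME=d.time, DV=None, DVID=None, AMT=d.amount, TINF=d.infusion_duration,
                 USTART=None, UVOL=None)
        rows.append(r)
    for o in dataset.observations:
        r = base(o.subject)
        r.update(TIME=o.time, DV=o.value, DVID=1 if o.kind == "plasma" else 2,
                 AMT=None, TINF=None, USTART=o.interval_start, UVOL=o.urine_volume)
        rows.append(r)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.sort_values(["ID", "TIME", "DVID"], inplace=True, kind="stable", na_position="first")
    df.to_csv(path, index=False)
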