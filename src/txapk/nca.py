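"""Noncompartmental analysis and bleeding-status group comparisons.

Exposure metrics are model-free functions of each subject's plasma
concentration-time points: partial AUCs from the end of the 1-min infusion
(T1) to 30 and 60 min, the (back-extrapolated) end-of-infusion peak C_T1,
interpolated C_T30/C_T60, a truncated mean residence time over the observed
span, and the terminal half-life from the last declining points. Integration
uses the linear-up / log-down trapezoidal rule: linear on rising or flat
segments, logarithmic on strictly declining positive segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["NCAMetrics", "compute_nca", "auc_linlog", "interpolate_conc",
           "compare_groups", "assign_bleeding_groups"]

T1_DEFAULT = 1.0  # min, end of the 1-minute infusion


@dataclass
class NCAMetrics:
    c_t1: float
    c_t30: float
    c_t60: float
    auc_t1_t30: float
    auc_t1_t60: float
    mrt: float
    half_life: float


def _segment_auc(t1, c1, t2, c2):
    """AUC of one segment: log trapezoid on strictly declining positive
    segments, linear otherwise."""
    dt = t2 - t1
    if c1 > c2 > 0:
        k = np.log(c1 / c2) / dt
        return (c1 - c2) / k
    return 0.5 * (c1 + c2) * dt


def _segment_aumc(t1, c1, t2, c2):
    dt = t2 - t1
    if c1 > c2 > 0:
        k = np.log(c1 / c2) / dt
        return (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    return 0.5 * (t1 * c1 + t2 * c2) * dt


def interpolate_conc(times, conc, t):
    """Concentration at time t under the integration rule: log-linear
    between declining positive samples, linear otherwise; log-linear
    back-extrapolation before the first sample and forward-extrapolation
    after the last (falling back to the nearest value when not declining)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if t <= times[0]:
        if len(times) >= 2 and conc[0] > conc[1] > 0:
            k = np.log(conc[0] / conc[1]) / (times[1] - times[0])
            return float(conc[0] * np.exp(k * (times[0] - t)))
        return float(conc[0])
    if t >= times[-1]:
        if len(times) >= 2 and conc[-2] > conc[-1] > 0:
            k = np.log(conc[-2] / conc[-1]) / (times[-1] - times[-2])
            return float(conc[-1] * np.exp(-k * (t - times[-1])))
        return float(conc[-1])
    j = int(np.searchsorted(times, t, side="right") - 1)
    t1, t2, c1, c2 = times[j], times[j + 1], conc[j], conc[j + 1]
    if c1 > c2 > 0:
        k = np.log(c1 / c2) / (t2 - t1)
        return float(c1 * np.exp(-k * (t - t1)))
    return float(c1 + (c2 - c1) * (t - t1) / (t2 - t1))


def auc_linlog(times, conc, t_start=None, t_end=None):
    """Linear-up/log-down trapezoidal AUC over [t_start, t_end].

    Boundaries not on sample points are included by interpolation with the
    same rule, so auc(a,b) + auc(b,c) = auc(a,c) whenever b is a sample
    point.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    t_start = times[0] if t_start is None else float(t_start)
    t_end = times[-1] if t_end is None else float(t_end)
    ts = [t_start] + [float(t) for t in times if t_start < t < t_end] + [t_end]
    cs = [interpolate_conc(times, conc, t) for t in ts]
    return float(sum(_segment_auc(ts[j], cs[j], ts[j + 1], cs[j + 1])
                     for j in range(len(ts) - 1)))


def compute_nca(times, concentrations, dose, t1: float = T1_DEFAULT) -> NCAMetrics:
    """Noncompartmental exposure metrics for one subject.

    ``times``/``concentrations`` are the observed plasma samples (sorted);
    ``dose`` is carried for interface completeness (the metrics themselves
    are dose-free). The terminal half-life uses a log-linear regression on
    the last three declining positive samples and is NaN when unavailable;
    the MRT is truncated to the observed span (no extrapolation to
    infinity).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    order = np.argsort(t)
    t, c = t[order], c[order]

    c_t1 = interpolate_conc(t, c, t1)
    c_t30 = interpolate_conc(t, c, 30.0)
    c_t60 = interpolate_conc(t, c, 60.0)
    auc30 = auc_linlog(t, c, t1, 30.0)
    auc60 = auc_linlog(t, c, t1, 60.0)

    ts = [t1] + [float(x) for x in t if t1 < x < t[-1]] + [float(t[-1])]
    cs = [interpolate_conc(t, c, x) for x in ts]
    auc_span = sum(_segment_auc(ts[j], cs[j], ts[j + 1], cs[j + 1])
                   for j in range(len(ts) - 1))
    aumc_span = sum(_segment_aumc(ts[j], cs[j], ts[j + 1], cs[j + 1])
                    for j in range(len(ts) - 1))
    mrt = aumc_span / auc_span if auc_span > 0 else float("nan")

    half_life = float("nan")
    tail_t, tail_c = [], []
    for j in range(len(t) - 1, -1, -1):
        if c[j] <= 0:
            break
        if tail_c and c[j] <= tail_c[-1]:
            break
        tail_t.append(t[j])
        tail_c.append(c[j])
    if len(tail_t) >= 3:
        tt = np.array(tail_t[::-1][-3:])
        cc = np.array(tail_c[::-1][-3:])
        slope = np.polyfit(tt, np.log(cc), 1)[0]
        if slope < 0:
            half_life = float(np.log(2.0) / -slope)

    return NCAMetrics(c_t1=c_t1, c_t30=c_t30, c_t60=c_t60,
                      auc_t1_t30=auc30, auc_t1_t60=auc60,
                      mrt=float(mrt), half_life=half_life)


def assign_bleeding_groups(stopped_by: dict[str, float | None],
                           assessment: float) -> dict[str, str]:
    """Bleeding-status group labels at an assessment time (30 or 60 min).

    ``stopped_by`` maps subject -> time bleeding definitively stopped (None
    if bleeding continued). Group A: stopped at or before the assessment
    time and did not re-bleed; B: still bleeding; C: stopped but re-bled
    later; D (T60 only): stopped before T60 but re-bled at T60. Here
    re-bleeding is encoded by a negative stop time whose magnitude is the
    re-bleed time.
    """
    labels = {}
    for sid, stop in stopped_by.items():
        if stop is None:
            labels[sid] = "B"
        elif stop < 0:
            rebleed = -stop
            labels[sid] = "D" if (assessment >= 60.0 and rebleed <= assessment) else "C"
        elif stop <= assessment:
            labels[sid] = "A"
        else:
            labels[sid] = "B"
    return labels


def compare_groups(metrics: dict[str, float], groups: dict[str, str]) -> dict:
    """Kruskal-Wallis comparison of one NCA metric across bleeding groups.

    ``metrics`` maps subject -> metric value, ``groups`` maps subject ->
    group label. Returns the statistic, p-value and per-group summaries
    (median, Q1, Q3, n).
    """
    by_group: dict[str, list[float]] = {}
    for sid, v in metrics.items():
        if sid in groups and np.isfinite(v):
            by_group.setdefault(groups[sid], []).append(v)
    by_group = {g: v for g, v in by_group.items() if v}
    if len(by_group) < 2:
        raise ValueError("need at least 2 non-empty groups")
    samples = [np.asarray(v) for v in by_group.values()]
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0 or all(
            sorted(s.tolist()) == sorted(samples[0].tolist()) for s in samples[1:]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*samples)
    summary = {
        g: {"n": len(v), "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)), "q3": float(np.percentile(v, 75))}
        for g, v in by_group.items()
    }
    return {"statistic": float(stat), "p_value": float(p), "groups": summary}
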