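"""Cohort summaries and paired camera comparisons.

Metrics from many acquisitions are aggregated as mean ± sample SD and
compared between the two cameras with a paired t test (two-sided,
significance at P < .05, no multiple-testing correction). Localization
is an angle, so its summaries use circular statistics and its paired
differences are taken as signed shortest angular differences before the
t test, avoiding wrap artifacts near 0/360.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def mean_sd(values, circular: bool = False) -> tuple[float, float]:
    """Mean and sample SD (n-1); circular versions for angular data.

    The circular mean is the direction of the resultant vector; the
    circular SD is ``sqrt(-2 ln R)`` with ``R`` the mean resultant
    length, expressed in degrees.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if circular:
        z = np.exp(1j * np.radians(v)).mean()
        mean = float(np.degrees(np.angle(z)) % 360.0)
        if mean >= 360.0 - 1e-12:
            mean = 0.0
        r = np.abs(z)
        sd = float(np.degrees(np.sqrt(-2.0 * np.log(r)))) if r > 0 else float("inf")
        return mean, sd
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return mean, sd


def circular_difference_deg(a, b) -> np.ndarray:
    """Signed shortest angular difference a - b, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


@dataclass(frozen=True)
class PairedMetricSample:
    """Aligned per-subject metric values for two cameras."""

    subjects: tuple
    values_a: np.ndarray
    values_b: np.ndarray
    metric: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or len(self.subjects) != a.size:
            raise ValueError("samples must be 1-D, aligned by subject")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("missing pairs must be excluded before testing")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def differences(self) -> np.ndarray:
        if self.circular:
            return circular_difference_deg(self.values_a, self.values_b)
        return self.values_a - self.values_b


@dataclass(frozen=True)
class PairedTResult:
    t: float
    dof: int
    p: float
    mean_difference: float
    degenerate: bool = False


def paired_t(sample: PairedMetricSample) -> PairedTResult:
    """Two-sided paired t test on the per-subject differences.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``dof = n - 1``; the p
    value comes from the t-distribution survival function. All-zero
    differences are degenerate: reported as t = 0, p = 1 with a flag.
    Swapping the cameras negates t and leaves p unchanged.
    """
    d = sample.differences
    n = d.size
    if n < 2:
        raise ValueError("paired t test requires n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTResult(t=0.0, dof=n - 1, p=1.0, mean_difference=0.0, degenerate=True)
        raise ValueError("zero-variance non-zero differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=t, dof=n - 1, p=p, mean_difference=float(d.mean()))


#: Metrics summarized per camera, with their angular flag.
_METRICS = (("extent_pct", False), ("depth_pct", False), ("localization_deg", True))


def summarize_cohort(
    metrics: pd.DataFrame, group_col: str = "camera", subject_col: str = "subject"
) -> dict:
    """Per-camera mean ± SD of extent, depth and localization, plus
    paired t tests across cameras where subject pairs exist.

    ``metrics`` needs one row per acquisition with columns
    ``extent_pct``, ``depth_pct``, ``localization_deg``, the grouping
    column and (for pairing) a subject column. Acquisitions with
    undefined metrics (empty masks) are dropped per metric. With a
    single acquisition in a group, the SD is null and no test is run.
    """
    out: dict = {"groups": {}, "paired_tests": {}}
    for g, sub in metrics.groupby(group_col):
        summary = {"n_acquisitions": int(len(sub))}
        for col, circular in _METRICS:
            vals = sub[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                summary[col] = None
                continue
            mean, sd = mean_sd(vals, circular=circular)
            summary[col] = {
                "mean": mean,
                "sd": None if (vals.size < 2 or not np.isfinite(sd)) else sd,
                "n": int(vals.size),
                "circular": circular,
            }
        out["groups"][str(g)] = summary

    groups = list(metrics[group_col].unique())
    if len(groups) == 2 and subject_col in metrics:
        a, b = groups
        wide = metrics.pivot_table(
            index=subject_col, columns=group_col, values=[c for c, _ in _METRICS]
        )
        for col, circular in _METRICS:
            try:
                pair = wide[col][[a, b]].dropna()
            except KeyError:
                continue
            if len(pair) < 2:
                continue
            sample = PairedMetricSample(
                subjects=tuple(pair.index),
                values_a=pair[a].to_numpy(),
                values_b=pair[b].to_numpy(),
                metric=col,
                circular=circular,
            )
            r = paired_t(sample)
            out["paired_tests"][col] = {
                "camera_a": str(a),
                "camera_b": str(b),
                "t": r.t,
                "dof": r.dof,
                "p": r.p,
                "mean_difference": r.mean_difference,
                "degenerate": r.degenerate,
                "significant_at_0.05": bool(r.p < 0.05),
            }
    return out
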