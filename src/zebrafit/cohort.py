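"""Cohort statistics over gestational age.

Three analyses are combined into the cohort report:

* **Cross-sectional**: ordinary least squares of a whole-organ metric on
  gestational age (GA, weeks) across subjects scanned once — slope,
  intercept, R^2 and the two-sided p-value of the slope (t distribution,
  n - 2 degrees of freedom).  A slope is called significant when
  p < 0.05 (strict).
* **Within-subject rates of change**: for subjects scanned twice in the
  same pregnancy, the per-week difference of the metric between the two
  scans.
* **Consistency ("covariance")**: the signed ratio SD/mean of the
  individual within-subject slopes — a coefficient of variation of rates
  of change.  Individual trends are called consistent when |SD/mean| < 1
  (strict): dispersion across subjects smaller than the common trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    DegenerateDesignError,
    PairingError,
    SampleSizeError,
    UndefinedStatisticError,
)
from .maps import METRIC_NAMES, ScanMetrics

__all__ = [
    "SubjectObservation",
    "CrossSectionalFit",
    "LongitudinalSummary",
    "ols_fit",
    "within_subject_slope",
    "consistency_statistic",
    "classify_significance",
    "cohort_report",
    "observations_from_frame",
]

GA_MIN_WEEKS = 20.0
GA_MAX_WEEKS = 42.0
P_SIGNIFICANT = 0.05
CONSISTENCY_LIMIT = 1.0


@dataclass(frozen=True)
class SubjectObservation:
    """One scan of one subject: gestational age plus whole-organ metrics."""

    subject_id: str
    ga_weeks: float
    metrics: ScanMetrics

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not GA_MIN_WEEKS <= self.ga_weeks <= GA_MAX_WEEKS:
            raise ValueError(
                f"gestational age {self.ga_weeks} weeks outside the inclusion "
                f"range [{GA_MIN_WEEKS}, {GA_MAX_WEEKS}]"
            )

    def value(self, metric: str) -> float:
        return self.metrics[metric]


@dataclass(frozen=True)
class CrossSectionalFit:
    """OLS of one metric on GA: y = intercept + slope * ga."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    significant: bool
    slope_ci: tuple = (math.nan, math.nan)  # 95% CI of the slope


@dataclass(frozen=True)
class LongitudinalSummary:
    """Distribution of within-subject rates of change for one metric."""

    slopes: tuple
    slope_mean: float
    slope_sd: float
    consistency: float
    consistent: bool


def ols_fit(ga: Sequence[float], y: Sequence[float]) -> CrossSectionalFit:
    """Ordinary least squares of ``y`` on gestational age.

    R^2 is 1 - SS_res/SS_tot; if y is constant (SS_tot = 0) the fit is
    defined as slope 0, R^2 = 0, p = 1.  Requires n >= 3 and a
    non-constant GA design.
    """
    ga = np.asarray(ga, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if ga.size != y.size:
        raise ValueError(f"length mismatch: {ga.size} GA values, {y.size} y values")
    n = ga.size
    if n < 3:
        raise SampleSizeError(f"OLS over GA needs n >= 3 scans, got {n}")
    if np.ptp(ga) == 0:
        raise DegenerateDesignError("all gestational ages equal; slope undefined")
    if np.ptp(y) == 0:
        return CrossSectionalFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                 p_value=1.0, n=n, significant=False,
                                 slope_ci=(0.0, 0.0))
    res = sm.OLS(y, sm.add_constant(ga)).fit()
    slope = float(res.params[1])
    p = float(res.pvalues[1])
    ci = res.conf_int(alpha=0.05)
    return CrossSectionalFit(
        slope=slope,
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=p,
        n=n,
        significant=bool(p < P_SIGNIFICANT),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
    )


def within_subject_slope(obs1: SubjectObservation, obs2: SubjectObservation,
                         metric: str) -> float:
    """Rate of change of ``metric`` between two scans of one subject,
    metric units per week, ordered by gestational age."""
    if obs1.subject_id != obs2.subject_id:
        raise PairingError(
            f"scans belong to different subjects: {obs1.subject_id!r} vs "
            f"{obs2.subject_id!r}"
        )
    if obs1.ga_weeks == obs2.ga_weeks:
        raise PairingError(
            f"both scans of {obs1.subject_id!r} at GA {obs1.ga_weeks} weeks; "
            "rate of change undefined"
        )
    first, second = sorted((obs1, obs2), key=lambda o: o.ga_weeks)
    return (second.value(metric) - first.value(metric)) / (
        second.ga_weeks - first.ga_weeks
    )


def consistency_statistic(slopes: Sequence[float]) -> LongitudinalSummary:
    """Signed SD/mean of within-subject slopes (sample SD, n - 1).

    The sign follows the mean slope; consistency holds when the absolute
    ratio is strictly below 1.
    """
    arr = np.asarray(slopes, dtype=float).ravel()
    if arr.size < 2:
        raise SampleSizeError(
            f"consistency needs >= 2 within-subject slopes, got {arr.size}"
        )
    mean = float(arr.mean())
    if mean == 0.0:
        raise UndefinedStatisticError("mean within-subject slope is zero")
    sd = float(arr.std(ddof=1))
    ratio = sd / mean
    return LongitudinalSummary(
        slopes=tuple(float(v) for v in arr),
        slope_mean=mean,
        slope_sd=sd,
        consistency=ratio,
        consistent=bool(abs(ratio) < CONSISTENCY_LIMIT),
    )


def classify_significance(fit: Optional[CrossSectionalFit] = None,
                          summary: Optional[LongitudinalSummary] = None) -> dict:
    """Apply the strict significance rules: p < 0.05 and |SD/mean| < 1."""
    flags = {}
    if fit is not None:
        flags["regression_significant"] = bool(fit.p_value < P_SIGNIFICANT)
    if summary is not None:
        flags["longitudinally_consistent"] = bool(
            abs(summary.consistency) < CONSISTENCY_LIMIT
        )
    return flags


def _pair_by_subject(long_obs: Sequence[SubjectObservation]):
    by_subject: dict = {}
    for obs in long_obs:
        by_subject.setdefault(obs.subject_id, []).append(obs)
    pairs = []
    for sid, scans in by_subject.items():
        if len(scans) != 2:
            raise PairingError(
                f"subject {sid!r} has {len(scans)} scans; longitudinal "
                "analysis expects exactly 2 per subject"
            )
        pairs.append(tuple(sorted(scans, key=lambda o: o.ga_weeks)))
    return pairs


def cohort_report(cross_obs: Sequence[SubjectObservation],
                  long_obs: Sequence[SubjectObservation] = (),
                  metrics: Sequence[str] = METRIC_NAMES) -> pd.DataFrame:
    """One row per metric: within-subject slope mean +/- SD with the
    consistency ratio, and the cross-sectional slope with [R^2, p].

    Metrics absent from any scan are reported with NaN cells rather than
    failing the whole report.
    """
    pairs = _pair_by_subject(long_obs)
    rows = []
    for metric in metrics:
        row: dict = {"metric": metric}
        try:
            ga = [o.ga_weeks for o in cross_obs]
            y = [o.value(metric) for o in cross_obs]
            fit = ols_fit(ga, y)
            row.update(
                cs_slope=fit.slope, cs_intercept=fit.intercept,
                r_squared=fit.r_squared, p_value=fit.p_value,
                n_cross=fit.n, significant=fit.significant,
            )
        except (KeyError, SampleSizeError, DegenerateDesignError):
            row.update(cs_slope=np.nan, cs_intercept=np.nan, r_squared=np.nan,
                       p_value=np.nan, n_cross=len(cross_obs), significant=False)
        try:
            slopes = [within_subject_slope(a, b, metric) for a, b in pairs]
            summary = consistency_statistic(slopes)
            row.update(
                long_slope_mean=summary.slope_mean,
                long_slope_sd=summary.slope_sd,
                consistency=summary.consistency,
                consistent=summary.consistent,
                n_long=len(slopes),
            )
        except (KeyError, SampleSizeError, UndefinedStatisticError):
            row.update(long_slope_mean=np.nan, long_slope_sd=np.nan,
                       consistency=np.nan, consistent=False,
                       n_long=len(pairs))
        rows.append(row)
    return pd.DataFrame(rows)


def observations_from_frame(frame: pd.DataFrame) -> list[SubjectObservation]:
    """Build observations from a metrics table (one row per scan).

    Required columns: ``subject_id``, ``ga_weeks``; every other numeric
    column is treated as a metric.
    """
    required = {"subject_id", "ga_weeks"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metrics table is missing columns {sorted(missing)}")
    metric_cols = [c for c in frame.columns if c not in required
                   and c != "n_voxels_used"]
    obs = []
    for _, row in frame.iterrows():
        values = {c: float(row[c]) for c in metric_cols if pd.notna(row[c])}
        n_vox = int(row["n_voxels_used"]) if "n_voxels_used" in frame.columns else 1
        obs.append(SubjectObservation(
            subject_id=str(row["subject_id"]),
            ga_weeks=float(row["ga_weeks"]),
            metrics=ScanMetrics(values=values, n_voxels_used=max(n_vox, 1)),
        ))
    return obs
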