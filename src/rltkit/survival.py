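"""Survival-based efficacy statistics for preclinical therapy arms.

Animals reaching the humane endpoint (a body-weight loss of 20% or more
relative to the inoculation-day baseline) are treated as events, the same
as deaths; animals alive at study end are censored at last observation.
The module provides the Kaplan-Meier product-limit estimator, the median
survival defined as the smallest time at which the survivor function is
less than or equal to 0.5, the two-group log-rank (Mantel-Cox) test with
hypergeometric variance, and the percent lifespan increase of a treated
arm over control.

The log-rank statistic and product-limit curve are computed directly from
their defining sums (risk sets over pooled event times) rather than
delegated, so the test suite can cross-check them against an independent
survival-analysis library and a brute-force enumeration oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import AnalysisError, InputError

__all__ = [
    "SubjectRecord",
    "KMCurve",
    "humane_endpoint_events",
    "km_curve",
    "median_survival",
    "logrank",
    "lifespan_increase",
    "group_summary",
    "read_subjects",
]

#: Humane-endpoint body-weight-loss threshold (fraction of baseline).
WEIGHT_LOSS_THRESHOLD = 0.20


@dataclass(frozen=True)
class SubjectRecord:
    """One animal's survival record; ``event`` False means censored."""

    id: str
    group: str
    time_days: float
    event: bool
    weights: tuple[tuple[float, float], ...] = ()  # (day, grams)

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise InputError(f"survival time must be positive for {self.id!r}")
        for _, g in self.weights:
            if g < 0:
                raise InputError("body weights must be >= 0")


@dataclass
class KMCurve:
    """Kaplan-Meier step function: S(t) after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t) with S(0) = 1 and right-continuous steps."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def humane_endpoint_events(
    weights: list[tuple[float, float]],
    baseline_day: float,
    threshold: float = WEIGHT_LOSS_THRESHOLD,
) -> float | None:
    """First day the body weight drops to <= (1 - threshold) x baseline.

    The boundary is inclusive (a loss of exactly the threshold triggers the
    endpoint).  Returns None if the series never crosses, or is empty.
    """
    if not weights:
        return None
    series = sorted(weights)
    baseline = next((g for day, g in series if day == baseline_day), None)
    if baseline is None:
        raise InputError(f"no weight measured on baseline day {baseline_day}")
    if baseline <= 0:
        raise InputError("baseline weight must be positive")
    cutoff = (1.0 - threshold) * baseline
    for day, g in series:
        if day > baseline_day and g <= cutoff:
            return day
    return None


def km_curve(records: list[SubjectRecord]) -> KMCurve:
    """Product-limit survivor estimate.

    At each distinct event time t with d deaths out of n at risk,
    S multiplies by (1 - d/n).  Censored subjects leave the risk set
    without a step; a death and a censoring tied at t count the censored
    subject as still at risk (death processed first).
    """
    if not records:
        raise InputError("need at least one subject")
    times = np.array([r.time_days for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events])
    surv, risks = [], []
    s = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risks.append(n_at_risk)
    return KMCurve(
        event_times=event_times.astype(float),
        survival=np.array(surv),
        at_risk=np.array(risks),
        n_subjects=len(records),
    )


def median_survival(c: KMCurve) -> float | None:
    """Smallest survival time with S(t) <= 0.5; None if never reached."""
    for t, s in zip(c.event_times, c.survival):
        if s <= 0.5 + 1e-12:
            return float(t)
    return None


def logrank(
    a: list[SubjectRecord], b: list[SubjectRecord]
) -> tuple[float, float, int]:
    """Two-group log-rank test: (chi_square, p, df=1).

    Over the pooled distinct event times, U is the observed-minus-expected
    event count in group a and V the sum of hypergeometric variances
    (ties handled with multiplicities); chi2 = U^2/V with 1 df.
    """
    if not a or not b:
        raise InputError("both groups must be non-empty")
    times = np.array([r.time_days for r in a + b])
    events = np.array([r.event for r in a + b])
    in_a = np.array([True] * len(a) + [False] * len(b))
    pooled_event_times = np.unique(times[events])
    if pooled_event_times.size == 0:
        raise AnalysisError("no events in either group; log-rank undefined")
    u = 0.0
    v = 0.0
    for t in pooled_event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((times == t) & events).sum())
        d_a = int(((times == t) & events & in_a).sum())
        u += d_a - d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0, 1
    stat = u * u / v
    p = float(chi2.sf(stat, df=1))
    return float(stat), p, 1


def lifespan_increase(median_treated: float | None, median_control: float | None) -> float:
    """Percent lifespan increase, 100 x (treated - control)/control."""
    if median_treated is None or median_control is None:
        raise AnalysisError("median survival not reached; increase not computable")
    if median_control <= 0:
        raise InputError("control median must be positive")
    return 100.0 * (median_treated - median_control) / median_control


def group_summary(
    records: list[SubjectRecord], control_group: str | None = None
) -> pd.DataFrame:
    """Per-group n, events, median survival and lifespan increase vs control.

    Percentages are reported to one decimal (round-half-even).  Medians not
    reached appear as NaN.
    """
    groups: dict[str, list[SubjectRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    control_median = None
    if control_group is not None:
        if control_group not in groups:
            raise InputError(f"control group {control_group!r} not found")
        control_median = median_survival(km_curve(groups[control_group]))
    rows = []
    for name in sorted(groups):
        recs = groups[name]
        med = median_survival(km_curve(recs))
        inc = math.nan
        if (
            control_median is not None
            and med is not None
            and name != control_group
        ):
            inc = round(lifespan_increase(med, control_median), 1)
        rows.append(
            {
                "group": name,
                "n": len(recs),
                "events": sum(r.event for r in recs),
                "median_days": math.nan if med is None else med,
                "lifespan_increase_pct": inc,
            }
        )
    return pd.DataFrame.from_records(rows)


def read_subjects(path: str) -> list[SubjectRecord]:
    """Read an ``id,group,time_days,event`` CSV into subject records."""
    df = pd.read_csv(path, comment="#")
    needed = {"id", "group", "time_days", "event"}
    if not needed <= set(df.columns):
        raise InputError(f"subjects CSV {path} must have columns {sorted(needed)}")
    return [
        SubjectRecord(
            id=str(r["id"]),
            group=str(r["group"]),
            time_days=float(r["time_days"]),
            event=bool(int(r["event"])),
        )
        for _, r in df.iterrows()
    ]
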