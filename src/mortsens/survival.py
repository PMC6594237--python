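"""Kaplan-Meier median survival and Cox hazard-ratio estimation.

Thin, contract-enforcing wrappers around lifelines.  Times enter in days;
median survival is reported in months (30.4375 days/month).  The median is
the smallest time at which the product-limit curve falls to 0.5 or below;
if the curve never reaches 0.5 the median (and its upper bound) is open,
represented as ``inf``.  The median CI inverts the log-log-transformed
Greenwood pointwise bounds (Brookmeyer-Crowley style).  Cox models use the
Efron tie correction, the appropriate default for integer-day data where
ties are guaranteed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times

from .cohort import DAYS_PER_MONTH


class EstimationError(ValueError):
    """Estimator preconditions violated (single arm, no events in an arm ...)."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One analysis row: time on study (days), event indicator, arm label."""

    time: float
    event: bool
    arm: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise EstimationError("time must be positive")


@dataclass(frozen=True)
class EstimateWithCI:
    """Point estimate with a 95% interval; ``inf`` bounds mean 'open'."""

    value: float
    ci_lower: float
    ci_upper: float
    n: int
    n_events: int

    def to_dict(self) -> dict:
        def _num(x: float) -> Optional[float]:
            return None if math.isinf(x) else x

        return {
            "value": _num(self.value),
            "ci_lower": _num(self.ci_lower),
            "ci_upper": _num(self.ci_upper),
            "n": self.n,
            "n_events": self.n_events,
        }


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "arm": [r.arm for r in records],
        }
    )


def km_median(records: Sequence[SurvivalRecord]) -> EstimateWithCI:
    """Median overall survival (months) from the product-limit curve.

    With zero events the median is undefined: the estimate and both bounds
    come back ``inf`` (flagged, not raised), mirroring how an open upper
    bound is reported when the curve never reaches 0.5.
    """
    if len(records) == 0:
        raise EstimationError("no records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    n_events = int(events.sum())
    if n_events == 0:
        return EstimateWithCI(math.inf, math.inf, math.inf, len(records), 0)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    median_days = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo_days = float(ci.iloc[0, 0])
    hi_days = float(ci.iloc[0, 1])
    return EstimateWithCI(
        value=median_days / DAYS_PER_MONTH,
        ci_lower=lo_days / DAYS_PER_MONTH,
        ci_upper=hi_days / DAYS_PER_MONTH,
        n=len(records),
        n_events=n_events,
    )


def cox_hr(records: Sequence[SurvivalRecord], reference_arm: str) -> EstimateWithCI:
    """Hazard ratio (non-reference vs reference arm) from a Cox model.

    Single binary covariate; HR = exp of the partial-likelihood MLE with the
    Efron tie correction and a 95% Wald interval.  Swapping the arm labels
    inverts the HR and its interval.
    """
    df = records_to_frame(records)
    labels = sorted(df["arm"].unique())
    if len(labels) != 2:
        raise EstimationError(f"cox_hr needs exactly two arms, got {labels}")
    if reference_arm not in labels:
        raise EstimationError(f"reference arm {reference_arm!r} not in {labels}")
    events_by_arm = df.groupby("arm")["event"].sum()
    if (events_by_arm == 0).any():
        bad = events_by_arm[events_by_arm == 0].index.tolist()
        raise EstimationError(
            f"no events in arm(s) {bad}: partial likelihood does not converge"
        )
    df = df.assign(treated=(df["arm"] != reference_arm).astype(int)).drop(columns="arm")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary.loc["treated"]
    return EstimateWithCI(
        value=float(summary["exp(coef)"]),
        ci_lower=float(summary["exp(coef) lower 95%"]),
        ci_upper=float(summary["exp(coef) upper 95%"]),
        n=len(records),
        n_events=int(df["event"].sum()),
    )
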