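"""Observed capacity versus published recovery-plan targets.

The Scottish Government's NHS recovery plan (August 2021) set explicit
elective-capacity targets against pre-pandemic reference levels of 67,500
inpatient and 350,000 outpatient cases per quarter: capacity was to reach
74,375 inpatients and 364,500 outpatients in April-June 2022, and then to
keep growing by 7,625 inpatients and 17,071 outpatients per quarter
through the last quarter of 2023.  This module compares an observed
quarterly capacity series against such a target trajectory: per-quarter
percentage shortfalls, the achieved mean quarterly increase (regression
slope by default, endpoint difference as an alternative — the two agree
on exactly linear series), and the shortfall of that increase against the
envisaged one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import QUARTER_FREQ, as_quarter

__all__ = [
    "RecoveryTargets",
    "PLAN_ANCHORS",
    "quarter_shortfall",
    "mean_quarterly_increase",
    "increase_shortfall",
    "assess_recovery",
]

#: published plan anchors per elective type: pre-pandemic quarterly
#: reference, the April-June 2022 target, and the envisaged per-quarter
#: increase through 2023Q4
PLAN_ANCHORS: Mapping[str, Mapping[str, float]] = {
    "inpatient": {
        "prepandemic_quarterly": 67_500,
        "target_2022q2": 74_375,
        "quarterly_increase": 7_625,
    },
    "outpatient": {
        "prepandemic_quarterly": 350_000,
        "target_2022q2": 364_500,
        "quarterly_increase": 17_071,
    },
}

PLAN_WINDOW = ("2022Q2", "2023Q4")  # seven quarters


@dataclass(frozen=True)
class RecoveryTargets:
    """Target capacity trajectory for one elective type.

    The shipped defaults linearly extend the published anchor quarter by
    the envisaged per-quarter increase; an arbitrary target series can be
    supplied instead (the plan's exact quarterly profile is configurable,
    the printed anchors are the defaults).
    """

    elective_type: str
    targets: pd.Series  # indexed by quarter
    envisaged_increase: float

    def __post_init__(self):
        if (self.targets <= 0).any():
            raise ValueError("targets must be positive")

    @classmethod
    def from_plan(
        cls,
        elective_type: str,
        window: tuple = PLAN_WINDOW,
        anchors: Mapping[str, Mapping[str, float]] = PLAN_ANCHORS,
    ) -> "RecoveryTargets":
        if elective_type not in anchors:
            raise KeyError(
                f"no plan anchors for {elective_type!r}; have {sorted(anchors)}"
            )
        a = anchors[elective_type]
        lo, hi = as_quarter(window[0]), as_quarter(window[1])
        idx = pd.period_range(start=lo, end=hi, freq=QUARTER_FREQ)
        vals = a["target_2022q2"] + a["quarterly_increase"] * np.arange(len(idx))
        return cls(
            elective_type=elective_type,
            targets=pd.Series(vals, index=idx, name="target"),
            envisaged_increase=float(a["quarterly_increase"]),
        )


def quarter_shortfall(observed: float, target: float, decimals: int = 0) -> float:
    """Percentage shortfall of observed capacity against a target:
    100 * (target - observed) / target.  A surplus reports negative."""
    if not np.isfinite(target) or target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    return float(np.round(100.0 * (target - observed) / target, decimals))


def mean_quarterly_increase(observed: Sequence[float], method: str = "slope") -> float:
    """Achieved mean per-quarter capacity increase over a window.

    ``method='slope'`` (default) is the least-squares slope of observed
    capacity on quarter index; ``method='endpoint'`` divides the endpoint
    difference by the number of gaps.  Both equal the true increment on an
    exactly linear series.
    """
    vals = np.asarray(
        observed.to_numpy() if isinstance(observed, pd.Series) else observed,
        dtype=float,
    )
    if len(vals) < 2:
        raise ValueError("need at least two quarters to estimate an increase")
    if method == "slope":
        x = np.arange(len(vals), dtype=float)
        slope, _ = np.polyfit(x, vals, deg=1)
        return float(slope)
    if method == "endpoint":
        return float((vals[-1] - vals[0]) / (len(vals) - 1))
    raise ValueError(f"unknown method {method!r}")


def increase_shortfall(observed: float, envisaged: float, decimals: int = 0) -> float:
    """Percentage shortfall of the achieved capacity increase against the
    envisaged one: 100 * (envisaged - observed) / envisaged."""
    if not np.isfinite(envisaged) or envisaged <= 0:
        raise ValueError(f"envisaged increase must be positive, got {envisaged}")
    return float(np.round(100.0 * (envisaged - observed) / envisaged, decimals))


def assess_recovery(
    observed: pd.Series,
    targets: RecoveryTargets,
    *,
    increase_method: str = "slope",
) -> dict:
    """Full recovery assessment for one elective type.

    Returns a dict with a tidy per-quarter frame (observed, target,
    shortfall_pct) restricted to the aligned window, plus the achieved
    mean quarterly increase (its estimator recorded), the envisaged
    increase, and the increase shortfall.
    """
    observed = observed.copy()
    observed.index = pd.PeriodIndex(observed.index, freq=QUARTER_FREQ)
    idx = targets.targets.index.intersection(observed.index)
    if len(idx) < 2:
        raise ValueError("observed series overlaps the target window in <2 quarters")
    obs, tgt = observed.loc[idx], targets.targets.loc[idx]
    per_quarter = pd.DataFrame(
        {
            "quarter": idx,
            "observed": obs.to_numpy(),
            "target": tgt.to_numpy(),
            "shortfall_pct": [
                quarter_shortfall(o, t) for o, t in zip(obs, tgt)
            ],
        }
    )
    achieved = mean_quarterly_increase(obs, method=increase_method)
    return {
        "elective_type": targets.elective_type,
        "per_quarter": per_quarter,
        "observed_increase": achieved,
        "increase_method": increase_method,
        "envisaged_increase": targets.envisaged_increase,
        "increase_shortfall_pct": increase_shortfall(
            achieved, targets.envisaged_increase
        ),
    }
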