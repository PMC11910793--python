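"""Monte Carlo projection of the waiting list under capacity scenarios.

A fitted (or postulated) VARX model is iterated forward over a projection
horizon with the flows set by policy: referral demand held at a baseline
level (optionally scaled for sensitivity analysis) and removals following
a linear capacity ramp that accumulates to a target fractional increase X
by the end of the horizon,

    removals[t] = baseline * (1 + X * t / H),   t = 1..H.

Each simulation adds innovations drawn from the fitted residual
covariance; trajectories are summarised by the 2.5th, 50th and 97.5th
percentiles per quarter (the interval between the outer two is the 95%
prediction interval).  Scenarios run with a common seed share identical
innovation draws (common random numbers), which makes comparisons across
the capacity grid — e.g. the search for the smallest X that returns the
median trajectory to its pre-pandemic reference level — deterministic in
the policy variable.

The module also provides the pre-pandemic linear counterfactual: a
straight-line extrapolation of the pending stock fitted over the
pre-shock window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import WaitlistPanel, as_quarter
from .varx import VARX

__all__ = [
    "ScenarioConfig",
    "ProjectionResult",
    "CounterfactualTrend",
    "build_capacity_path",
    "simulate_projection",
    "find_min_capacity_increase",
    "linear_counterfactual",
    "CAPACITY_GRID",
]

#: the default capacity-increase grid: 0 to 25% in five-point increments
CAPACITY_GRID = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)

#: demand sensitivity multipliers: -10%, -5%, baseline, +5%, +10%
DEMAND_MULTIPLIERS = (0.90, 0.95, 1.00, 1.05, 1.10)


@dataclass(frozen=True)
class ScenarioConfig:
    """One capacity-increase scenario.

    ``capacity_increase`` is the fraction of baseline capacity accumulated
    by the end of the horizon (0.20 = +20% at quarter H, ramped linearly);
    ``baseline_capacity`` and ``baseline_demand`` are the mean quarterly
    removals/additions over the baseline window (by convention the last
    complete calendar year of data); ``horizon`` is in quarters (12 = the
    three-year recovery-plan window); ``reference_level`` is the pending
    stock that counts as backlog clearance (the pre-pandemic level).
    """

    baseline_capacity: float
    baseline_demand: float
    capacity_increase: float = 0.0
    horizon: int = 12
    demand_multiplier: float = 1.0
    n_sims: int = 1000
    seed: int = 0
    ramp_shape: str = "linear"
    reference_level: float | None = None
    innovations: str = "gaussian"  # or "none", "bootstrap"

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be at least one quarter")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if self.baseline_capacity <= 0 or self.baseline_demand <= 0:
            raise ValueError("baseline capacity and demand must be positive")
        if self.capacity_increase < -1:
            raise ValueError("capacity cannot fall below zero (X < -1)")
        if self.ramp_shape != "linear":
            raise ValueError("only the linear-gradual ramp is implemented")
        if self.innovations not in ("gaussian", "none", "bootstrap"):
            raise ValueError(f"unknown innovation scheme {self.innovations!r}")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ProjectionResult:
    """Percentile trajectories and summary facts for one scenario."""

    quarters: tuple  # 1-based horizon steps or Periods
    p2_5: np.ndarray
    p50: np.ndarray
    p97_5: np.ndarray
    peak_value: float
    peak_quarter: object
    cleared: bool | None
    clearance_quarter: object | None
    scenario: ScenarioConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quarter": list(self.quarters),
                "p2.5": self.p2_5,
                "p50": self.p50,
                "p97.5": self.p97_5,
            }
        )


def build_capacity_path(
    baseline: float, increase: float, horizon: int
) -> np.ndarray:
    """Linear capacity ramp reaching ``baseline * (1 + increase)`` at the
    final quarter: removals[t] = baseline * (1 + increase * t / H)."""
    if baseline <= 0:
        raise ValueError("baseline capacity must be positive")
    if horizon < 1:
        raise ValueError("horizon must be at least one quarter")
    if increase < -1:
        raise ValueError("capacity cannot be negative (increase < -1)")
    t = np.arange(1, horizon + 1, dtype=float)
    return baseline * (1.0 + increase * t / horizon)


def _innovation_factor(sigma: np.ndarray) -> np.ndarray:
    """Factor F with F F' = Sigma, tolerating the degenerate Sigma = 0."""
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    vals, vecs = np.linalg.eigh(sigma)
    tol = -1e-8 * max(vals.max(), 1.0)
    if vals.min() < tol:
        raise ValueError("residual covariance is not positive semi-definite")
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def initial_lags_from_frame(frame: pd.DataFrame, fit: VARX) -> np.ndarray:
    """Most recent max-lag endogenous values, shape (max_lag, m); row l-1
    holds the value l quarters before the projection start."""
    max_lag = max(fit.lags_)
    cols = list(fit.endog_)
    tail = frame.loc[:, cols].to_numpy(dtype=float)[-max_lag:]
    if len(tail) < max_lag:
        raise ValueError(f"need {max_lag} trailing quarters, have {len(tail)}")
    return tail[::-1].copy()


def simulate_projection(
    fit: VARX,
    scenario: ScenarioConfig,
    initial_lags: np.ndarray,
    *,
    start: object | None = None,
    capacity_path: np.ndarray | None = None,
) -> ProjectionResult:
    """Monte Carlo projection of the pending stock under one scenario.

    The fitted equation is iterated ``horizon`` quarters ahead with
    exogenous additions = baseline_demand * demand_multiplier and removals
    on the capacity ramp; each of ``n_sims`` paths adds innovations drawn
    from N(0, Sigma) (or bootstrap-resampled residuals).  Pending is
    floored at zero.  Results are bit-reproducible under a fixed seed, and
    innovation draws depend only on the seed and horizon — not on the
    scenario's policy parameters — so a shared seed yields common random
    numbers across a capacity grid.
    """
    H, S = scenario.horizon, scenario.n_sims
    m = len(fit.endog_)
    max_lag = max(fit.lags_)
    initial_lags = np.asarray(initial_lags, dtype=float)
    if initial_lags.shape != (max_lag, m):
        raise ValueError(
            f"initial_lags must have shape ({max_lag}, {m}), got {initial_lags.shape}"
        )
    if capacity_path is None:
        capacity_path = build_capacity_path(
            scenario.baseline_capacity, scenario.capacity_increase, H
        )
    capacity_path = np.asarray(capacity_path, dtype=float)
    if len(capacity_path) < H:
        raise ValueError(
            f"capacity path covers {len(capacity_path)} quarters but the "
            f"horizon is {H}"
        )
    demand = scenario.baseline_demand * scenario.demand_multiplier

    rng = np.random.default_rng(scenario.seed)
    if scenario.innovations == "gaussian":
        factor = _innovation_factor(fit.sigma_)
        eps = rng.standard_normal((H, S, m)) @ factor.T
    elif scenario.innovations == "bootstrap":
        resid = fit.resid_.to_numpy()
        rows = rng.integers(0, len(resid), size=(H, S))
        eps = resid[rows]
    else:
        eps = np.zeros((H, S, m))

    # exogenous vector layout follows fit.exog_
    exog_cols = {name: i for i, name in enumerate(fit.exog_)}
    if set(exog_cols) != {"additions", "removals"}:
        raise ValueError(
            "scenario projection requires exogenous inputs (additions, removals)"
        )

    state = np.broadcast_to(initial_lags, (S, max_lag, m)).copy()
    trajectory = np.empty((H, S))
    for t in range(H):
        exog_t = np.zeros(len(fit.exog_))
        exog_t[exog_cols["additions"]] = demand
        exog_t[exog_cols["removals"]] = capacity_path[t]
        y = fit.step(state, exog_t) + eps[t]
        np.maximum(y, 0.0, out=y)
        state = np.concatenate([y[:, None, :], state[:, :-1, :]], axis=1)
        trajectory[t] = y.sum(axis=-1)

    p2_5, p50, p97_5 = np.percentile(trajectory, [2.5, 50.0, 97.5], axis=1)
    if start is not None:
        start_q = as_quarter(start)
        quarters = tuple(start_q + i + 1 for i in range(H))
    else:
        quarters = tuple(range(1, H + 1))
    peak_idx = int(np.argmax(p50))
    ref = scenario.reference_level
    cleared: bool | None = None
    clearance_quarter = None
    if ref is not None:
        below = np.flatnonzero(p50 <= ref)
        cleared = bool(below.size)
        if cleared:
            clearance_quarter = quarters[int(below[0])]
    return ProjectionResult(
        quarters=quarters,
        p2_5=p2_5,
        p50=p50,
        p97_5=p97_5,
        peak_value=float(p50[peak_idx]),
        peak_quarter=quarters[peak_idx],
        cleared=cleared,
        clearance_quarter=clearance_quarter,
        scenario=scenario,
        seed=scenario.seed,
    )


def find_min_capacity_increase(
    fit: VARX,
    scenario: ScenarioConfig,
    initial_lags: np.ndarray,
    *,
    grid: Sequence[float] = CAPACITY_GRID,
    reference_level: float | None = None,
    start: object | None = None,
) -> tuple[float | None, pd.DataFrame, dict[float, ProjectionResult]]:
    """Smallest grid capacity increase whose median trajectory clears the
    backlog (reaches the reference level) within the horizon.

    Every grid point is simulated with the scenario's seed, so the grid
    shares common random numbers.  Returns ``(min_x, table, results)``;
    ``min_x`` is None when no grid point clears (the table still reports
    peak value/date and clearance date per X).
    """
    grid = sorted(float(x) for x in grid)
    if not grid:
        raise ValueError("capacity grid must be non-empty")
    ref = scenario.reference_level if reference_level is None else reference_level
    if ref is None or ref <= 0:
        raise ValueError("a positive reference_level is required")
    rows = []
    results: dict[float, ProjectionResult] = {}
    min_x: float | None = None
    for x in grid:
        res = simulate_projection(
            fit,
            scenario.replace(capacity_increase=x, reference_level=ref),
            initial_lags,
            start=start,
        )
        results[x] = res
        rows.append(
            {
                "capacity_increase": x,
                "peak_value": res.peak_value,
                "peak_quarter": res.peak_quarter,
                "cleared": res.cleared,
                "clearance_quarter": res.clearance_quarter,
            }
        )
        if res.cleared and min_x is None:
            min_x = x
    return min_x, pd.DataFrame(rows), results


@dataclass(frozen=True)
class CounterfactualTrend:
    """Straight-line extrapolation of the pre-shock pending stock."""

    slope_per_quarter: float
    intercept: float
    trajectory: pd.Series
    window: tuple

    @property
    def slope_per_year(self) -> float:
        return 4.0 * self.slope_per_quarter


def linear_counterfactual(
    panel: WaitlistPanel | pd.Series,
    window: tuple,
    projection_end,
) -> CounterfactualTrend:
    """Least-squares line through the pending stock over ``window``
    (e.g. 2013Q1..2019Q4), extrapolated to ``projection_end`` — the
    no-shock counterfactual trajectory."""
    series = panel.series("pending") if isinstance(panel, WaitlistPanel) else panel
    lo, hi = as_quarter(window[0]), as_quarter(window[1])
    end = as_quarter(projection_end)
    sub = series[(series.index >= lo) & (series.index <= hi)]
    if len(sub) < 3:
        raise ValueError(
            f"fit window {lo}..{hi} has {len(sub)} quarters; need at least 3"
        )
    x = np.array([(q - lo).n for q in sub.index], dtype=float)
    slope, intercept = np.polyfit(x, sub.to_numpy(dtype=float), deg=1)
    full_index = pd.period_range(start=lo, end=end, freq=lo.freq)
    xs = np.arange(len(full_index), dtype=float)
    traj = pd.Series(intercept + slope * xs, index=full_index, name="counterfactual")
    return CounterfactualTrend(
        slope_per_quarter=float(slope),
        intercept=float(intercept),
        trajectory=traj,
        window=(lo, hi),
    )
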