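"""Descriptive comparisons of waiting-list activity between periods.

Covers the arithmetic behind period-comparison tables: quarterly means
with 95% confidence intervals (optionally seasonally adjusted), percentage
changes between reference years, wait-band exceedance metrics (share of
referrals waiting beyond a target such as 12 weeks, or beyond a year), and
stratified summary tables with threshold flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import STRATUM_KEYS, WaitBandTable, WaitlistPanel, as_quarter

__all__ = [
    "PeriodSummary",
    "ExceedanceResult",
    "quarterly_mean_ci",
    "percent_change",
    "exceedance",
    "stratified_table",
    "CI_STRATEGIES",
]


@dataclass(frozen=True)
class PeriodSummary:
    """Mean of the four quarterly values of a year with a 95% CI."""

    label: str
    mean: float
    ci_low: float
    ci_high: float
    n_quarters: int
    strategy: str

    def __post_init__(self):
        if not (self.ci_low <= self.mean + 1e-9 and self.mean <= self.ci_high + 1e-9):
            raise ValueError("confidence interval does not bracket the mean")


@dataclass(frozen=True)
class ExceedanceResult:
    count: int
    fraction: float

    def __iter__(self):
        yield self.count
        yield self.fraction


def _seasonal_offsets(window: pd.Series) -> np.ndarray:
    """Quarter-of-year offsets estimated from year-demeaned values.

    Demeaning each calendar year before averaging per quarter-of-year keeps
    a trend from contaminating the seasonal profile; offsets are recentred
    to sum to zero.
    """
    df = pd.DataFrame(
        {
            "value": window.to_numpy(dtype=float),
            "year": window.index.year,
            "qoy": window.index.quarter,
        }
    )
    df["demeaned"] = df["value"] - df.groupby("year")["value"].transform("mean")
    offsets = np.zeros(4)
    means = df.groupby("qoy")["demeaned"].mean()
    offsets[means.index.to_numpy() - 1] = means.to_numpy()
    return offsets - offsets.mean()


def _ci_seasonal(values: pd.Series, window: pd.Series) -> tuple[float, float, float]:
    offsets = _seasonal_offsets(window)
    adjusted = values.to_numpy(dtype=float) - offsets[values.index.quarter - 1]
    mean = float(values.mean())
    se = float(np.std(adjusted, ddof=1)) / np.sqrt(len(adjusted))
    half = stats.t.ppf(0.975, len(adjusted) - 1) * se
    return mean, mean - half, mean + half


def _ci_raw_t(values: pd.Series, window: pd.Series) -> tuple[float, float, float]:
    mean = float(values.mean())
    se = float(np.std(values.to_numpy(dtype=float), ddof=1)) / np.sqrt(len(values))
    half = stats.t.ppf(0.975, len(values) - 1) * se
    return mean, mean - half, mean + half


#: pluggable CI schemes; "seasonal" is the default, "raw_t" the plain
#: t-interval on the four raw quarterly values
CI_STRATEGIES: dict[str, Callable] = {"seasonal": _ci_seasonal, "raw_t": _ci_raw_t}


def quarterly_mean_ci(
    panel: WaitlistPanel | pd.Series,
    measure: str = "pending",
    year: int | None = None,
    *,
    strategy: str = "seasonal",
    season_window: tuple | None = None,
    **stratum: str,
) -> PeriodSummary:
    """Mean of the four quarterly values of ``year`` with a 95% CI.

    The mean is the arithmetic mean of the raw quarterly values; the CI is
    computed by the selected strategy (seasonally adjusted residuals by
    default, with the seasonal profile estimated over ``season_window`` —
    the whole series when not given).  A constant series yields a
    zero-width interval.  All four quarters of the year must be present.
    """
    if strategy not in CI_STRATEGIES:
        raise KeyError(f"unknown CI strategy {strategy!r}; have {sorted(CI_STRATEGIES)}")
    series = panel.series(measure, **stratum) if isinstance(panel, WaitlistPanel) else panel
    if year is None:
        raise ValueError("year is required")
    values = series[series.index.year == year]
    if len(values) != 4:
        raise ValueError(
            f"year {year} has {len(values)} quarters in the series; need all 4"
        )
    if season_window is not None:
        lo, hi = (as_quarter(season_window[0]), as_quarter(season_window[1]))
        window = series[(series.index >= lo) & (series.index <= hi)]
    else:
        window = series
    mean, lo, hi = CI_STRATEGIES[strategy](values, window)
    return PeriodSummary(
        label=str(year), mean=mean, ci_low=lo, ci_high=hi,
        n_quarters=4, strategy=strategy,
    )


def percent_change(before: float, after: float, decimals: int | None = 1) -> float:
    """100 * (after - before) / before, rounded for reporting.

    ``decimals=None`` returns the unrounded value; the default single
    decimal matches tabular reporting, whole percents (``decimals=0``)
    match in-text usage.
    """
    if not np.isfinite(before) or before <= 0:
        raise ValueError(f"'before' must be positive, got {before}")
    change = 100.0 * (after - before) / before
    return change if decimals is None else float(np.round(change, decimals))


def exceedance(
    bands: WaitBandTable,
    threshold_weeks: float,
    quarter,
    **stratum: str,
) -> ExceedanceResult:
    """Referrals waiting strictly beyond ``threshold_weeks`` in a quarter.

    The threshold must coincide with a band edge (no interpolation).
    Returns the count above the threshold and its fraction of the quarter
    total.
    """
    if float(threshold_weeks) not in bands.edges:
        raise ValueError(
            f"threshold {threshold_weeks} weeks is not a band edge {bands.edges}"
        )
    counts = bands.counts(quarter, **stratum)
    cut = bands.edges.index(float(threshold_weeks)) + 1
    over = int(counts[cut:].sum())
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"no referrals recorded in quarter {quarter}")
    return ExceedanceResult(count=over, fraction=over / total)


def stratified_table(
    panel: WaitlistPanel,
    by: Sequence[str] = ("hb_code",),
    measure: str = "pending",
    *,
    baseline_year: int,
    comparison_year: int,
    change_flag_pct: float = 100.0,
    bands: WaitBandTable | None = None,
    exceedance_threshold_weeks: float = 12,
    exceedance_flag_fraction: float = 0.60,
    ci_strategy: str = "seasonal",
) -> pd.DataFrame:
    """One row per stratum with the same statistics as the national table.

    Each row carries the yearly quarterly means (with CI) for the baseline
    and comparison years, the percentage change, and a flag when the change
    exceeds ``change_flag_pct``.  When a band table is supplied, the
    comparison-year final-quarter exceedance fraction and its flag are
    added.  Empty strata are emitted with missing markers, not dropped.
    """
    by = list(by)
    bad = set(by) - set(STRATUM_KEYS)
    if bad:
        raise KeyError(f"unknown stratum keys: {sorted(bad)}")
    groups = panel.data[by].drop_duplicates().itertuples(index=False)
    rows = []
    for key in groups:
        sel = dict(zip(by, key))
        row: dict = dict(sel)
        try:
            base = quarterly_mean_ci(
                panel, measure, baseline_year, strategy=ci_strategy, **sel
            )
            comp = quarterly_mean_ci(
                panel, measure, comparison_year, strategy=ci_strategy, **sel
            )
        except (ValueError, KeyError):
            row.update(
                {
                    f"mean_{baseline_year}": np.nan,
                    f"mean_{comparison_year}": np.nan,
                    "pct_change": np.nan,
                    "flag_change": pd.NA,
                }
            )
            rows.append(row)
            continue
        change = percent_change(base.mean, comp.mean)
        row.update(
            {
                f"mean_{baseline_year}": base.mean,
                f"ci_low_{baseline_year}": base.ci_low,
                f"ci_high_{baseline_year}": base.ci_high,
                f"mean_{comparison_year}": comp.mean,
                f"ci_low_{comparison_year}": comp.ci_low,
                f"ci_high_{comparison_year}": comp.ci_high,
                "pct_change": change,
                "flag_change": bool(change > change_flag_pct),
            }
        )
        if bands is not None:
            last_q = as_quarter(f"{comparison_year}Q4")
            try:
                exc = exceedance(bands, exceedance_threshold_weeks, last_q, **sel)
                row["exceedance_fraction"] = exc.fraction
                row["flag_exceedance"] = bool(
                    exc.fraction > exceedance_flag_fraction
                )
            except (KeyError, ValueError):
                row["exceedance_fraction"] = np.nan
                row["flag_exceedance"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)
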