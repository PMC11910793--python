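"""Synthetic waiting-list panels with the structure the analysis assumes.

The generator emulates, at national scale, the regimes seen in Scotland's
elective-care data over 2013-2023: a slowly growing pending stock driven by
a small positive gap between referral inflow and realised throughput,
additive quarter-of-year seasonality in both flows, a sudden capacity
collapse early in 2020 with a fast but only partial recovery, and exact
stock-flow conservation

    pending[t] = pending[t-1] + additions[t] - removals[t].

Both flows are shocked: throughput collapses deeply (the default depth of
0.67 matches the scale of the observed trough) and then recovers quickly to
a plateau below its old baseline, while referral inflow dips less deeply
and recovers to a slightly higher plateau, leaving a persistent net inflow
several times the pre-shock one.  The shock law for a flow with baseline
``b`` is

    mean[t] = b * (1 - depth * (1 - min(rate * q, max_recovery))) + season

for ``q = t - shock_quarter >= 0`` quarters since the shock, i.e. a linear
recovery of the lost fraction that saturates at ``max_recovery`` (a value
of 1 recovers fully).

Counts are drawn as Gaussian-perturbed means, floored at zero, rounded
half-to-even, and the pending stock is then recomputed from the rounded
flows so conservation holds exactly on the integers.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import (
    STRATUM_KEYS,
    BandReconciliationError,
    WaitBandTable,
    WaitlistPanel,
    as_quarter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Stratum",
    "SyntheticConfig",
    "generate_panel",
    "generate_wait_bands",
    "simulate_varx_frame",
    "save_synthetic_dataset",
]


@dataclass(frozen=True)
class Stratum:
    """One (elective type, health board, specialty) cell with its share of
    the national totals."""

    elective_type: str
    hb_code: str
    specialty: str
    weight: float

    def key(self) -> tuple[str, str, str]:
        return (self.elective_type, self.hb_code, self.specialty)


DEFAULT_STRATA = (
    Stratum("inpatient", "Scotland", "all", 0.16),
    Stratum("outpatient", "Scotland", "all", 0.84),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults describe the study conditions: 44 quarters starting 2013Q1 at
    national scale (flows ~430k referrals/quarter, initial stock 255k, net
    inflow ~3.8k/quarter), with the capacity shock landing at index 29
    (2020Q2).  Seasonal offsets are additive and sum to zero over the four
    quarters of the year.
    """

    n_quarters: int = 44
    start_quarter: str = "2013Q1"
    baseline_additions: float = 436_000.0
    baseline_removals: float = 432_200.0
    inflow_trend: float = 0.0
    seasonal_additions: tuple[float, float, float, float] = (6_000.0, 1_000.0, -9_000.0, 2_000.0)
    seasonal_removals: tuple[float, float, float, float] = (10_000.0, 4_000.0, -18_000.0, 4_000.0)
    shock_quarter: int | None = 29
    shock_depth: float = 0.67
    recovery_rate: float = 0.25
    max_recovery: float = 0.78
    additions_shock_depth: float = 0.60
    additions_recovery_rate: float = 0.30
    additions_max_recovery: float = 0.79
    noise_sd_additions: float = 4_000.0
    noise_sd_removals: float = 4_000.0
    initial_pending: float = 255_000.0
    strata: tuple[Stratum, ...] = DEFAULT_STRATA
    seed: int = 0

    def __post_init__(self):
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be positive")
        if self.initial_pending < 0:
            raise ValueError("initial_pending must be non-negative")
        for name in ("noise_sd_additions", "noise_sd_removals"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "shock_depth",
            "recovery_rate",
            "max_recovery",
            "additions_shock_depth",
            "additions_recovery_rate",
            "additions_max_recovery",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        scale = max(abs(self.baseline_additions), abs(self.baseline_removals), 1.0)
        for name in ("seasonal_additions", "seasonal_removals"):
            amps = getattr(self, name)
            if len(amps) != 4:
                raise ValueError(f"{name} needs exactly four quarter-of-year offsets")
            if abs(sum(amps)) > 1e-9 * scale:
                raise ValueError(f"{name} offsets must sum to zero")
        if not self.strata:
            raise ValueError("at least one stratum is required")
        for s in self.strata:
            if not math.isfinite(s.weight) or s.weight <= 0:
                raise ValueError(f"stratum {s.key()} has invalid weight {s.weight}")
        if self.shock_quarter is not None and not (
            0 <= self.shock_quarter < self.n_quarters
        ):
            raise ValueError("shock_quarter out of range")

    def normalised_weights(self) -> np.ndarray:
        w = np.array([s.weight for s in self.strata], dtype=float)
        return w / w.sum()


def _shock_multiplier(
    t: np.ndarray,
    shock_quarter: int | None,
    depth: float,
    rate: float,
    max_recovery: float,
) -> np.ndarray:
    """Multiplier applied to a flow baseline: 1 before the shock, then a
    linear recovery of the lost fraction capped at ``max_recovery``."""
    mult = np.ones_like(t, dtype=float)
    if shock_quarter is None or depth == 0.0:
        return mult
    q = t - shock_quarter
    post = q >= 0
    recovered = np.minimum(rate * q[post], max_recovery)
    mult[post] = 1.0 - depth * (1.0 - recovered)
    return mult


def generate_panel(config: SyntheticConfig) -> WaitlistPanel:
    """Draw a stock-flow panel under ``config``.

    Per stratum of weight w, flow means are w times the national means
    (baseline x shock multiplier + trend + seasonal offset) and innovation
    standard deviations are w times the national ones.  Negative draws are
    floored at zero (the shortfall is logged, not redistributed); removals
    exceeding the available stock are clamped so the pending count can
    never go negative.  Fixing the seed fixes every generated number.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_quarters)
    start = as_quarter(config.start_quarter)
    quarters = pd.period_range(start=start, periods=config.n_quarters, freq=start.freq)
    qoy = np.array([q.quarter - 1 for q in quarters])

    mult_rem = _shock_multiplier(
        t, config.shock_quarter, config.shock_depth, config.recovery_rate, config.max_recovery
    )
    mult_add = _shock_multiplier(
        t,
        config.shock_quarter,
        config.additions_shock_depth,
        config.additions_recovery_rate,
        config.additions_max_recovery,
    )
    seas_add = np.asarray(config.seasonal_additions)[qoy]
    seas_rem = np.asarray(config.seasonal_removals)[qoy]

    rows = []
    for stratum, w in zip(config.strata, config.normalised_weights()):
        mean_add = w * (
            (config.baseline_additions + config.inflow_trend * t) * mult_add + seas_add
        )
        mean_rem = w * (config.baseline_removals * mult_rem + seas_rem)
        add = mean_add + rng.normal(0.0, config.noise_sd_additions * w, config.n_quarters)
        rem = mean_rem + rng.normal(0.0, config.noise_sd_removals * w, config.n_quarters)

        shortfall = -(np.minimum(add, 0).sum() + np.minimum(rem, 0).sum())
        if shortfall > 0:
            logger.info(
                "stratum %s: floored negative draws totalling %.1f referrals",
                stratum.key(),
                shortfall,
            )
        add = np.round(np.maximum(add, 0.0)).astype("int64")
        rem = np.round(np.maximum(rem, 0.0)).astype("int64")

        pending = np.empty(config.n_quarters, dtype="int64")
        stock = int(np.round(w * config.initial_pending))
        for i in range(config.n_quarters):
            available = stock + add[i]
            if rem[i] > available:
                logger.info(
                    "stratum %s quarter %s: clamped removals %d to available stock %d",
                    stratum.key(),
                    quarters[i],
                    rem[i],
                    available,
                )
                rem[i] = available
            stock = available - rem[i]
            pending[i] = stock

        rows.append(
            pd.DataFrame(
                {
                    "quarter": quarters,
                    "elective_type": stratum.elective_type,
                    "hb_code": stratum.hb_code,
                    "specialty": stratum.specialty,
                    "additions": add,
                    "removals": rem,
                    "pending": pending,
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    return WaitlistPanel(frame, strict_conservation=True)


# ---------------------------------------------------------------------------
# Wait-duration bands
# ---------------------------------------------------------------------------


def _band_of_age(ages: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Map cohort age in quarters to a band index.

    A referral added in the current quarter (age 0) has waited at most one
    quarter, i.e. at most ~13 weeks, and is assigned to the first band for
    the conventional 12-week edge; in general an edge at w weeks splits
    cohorts at ceil(w / 13) quarters of age.
    """
    age_edges = np.array([math.ceil(e / 13.0) for e in edges])
    return np.searchsorted(age_edges, ages, side="right")


def _capped_apportion(total: int, weights: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` across cells, proportional to
    ``weights``, with per-cell caps.  Deterministic largest-remainder."""
    weights = np.asarray(weights, dtype=float)
    caps = np.asarray(caps, dtype="int64")
    alloc = np.zeros_like(caps)
    remaining = int(total)
    if remaining > caps.sum():
        raise ValueError("total exceeds the sum of caps")
    while remaining > 0:
        free = alloc < caps
        w = np.where(free, weights, 0.0)
        if w.sum() <= 0:
            w = np.where(free, 1.0, 0.0)
        ideal = remaining * w / w.sum()
        step = np.minimum(np.floor(ideal).astype("int64"), caps - alloc)
        if step.sum() == 0:
            order = np.argsort(-(ideal - np.floor(ideal)), kind="stable")
            for j in order:
                if remaining == 0:
                    break
                if alloc[j] < caps[j] and w[j] > 0:
                    alloc[j] += 1
                    remaining -= 1
            if remaining > 0:  # only zero-weight cells left
                for j in np.flatnonzero(alloc < caps):
                    take = min(remaining, caps[j] - alloc[j])
                    alloc[j] += take
                    remaining -= take
            continue
        alloc += step
        remaining -= int(step.sum())
    return alloc


def generate_wait_bands(
    panel: WaitlistPanel,
    aging_profile: Sequence[float] | np.ndarray,
    seed: int = 0,
    *,
    kind: str = "ongoing",
    edges: Sequence[float] = (12, 52),
) -> WaitBandTable:
    """Build a wait-band table consistent with a panel by cohort bookkeeping.

    Every referral is tracked by its entry quarter; initial stock is treated
    as having entered one quarter before the panel starts.  Each quarter the
    panel's removals are drawn from the cohorts with weights proportional to
    cohort size times the band's resolution propensity, using a
    deterministic capped apportionment, so band counts always sum exactly to
    the panel's pending stock (``kind='ongoing'``) or removals
    (``kind='completed'``).

    Parameters
    ----------
    aging_profile:
        Per-band continuation fractions in [0, 1] (the complement is the
        propensity to be resolved from that band).  A matrix of
        band-transition fractions is accepted; its row sums are used.
    seed:
        Accepted for interface stability; the allocation is deterministic.
    """
    del seed  # deterministic construction; see docstring
    edges = tuple(float(e) for e in edges)
    n_bands = len(edges) + 1
    profile = np.asarray(aging_profile, dtype=float)
    if profile.ndim == 2:
        profile = profile.sum(axis=1)
    if profile.shape != (n_bands,):
        raise ValueError(
            f"aging_profile must give one continuation fraction per band ({n_bands})"
        )
    if np.any(profile < 0) or np.any(profile > 1 + 1e-12):
        raise ValueError("aging_profile rows must be non-negative and sum to <= 1")
    resolve_propensity = 1.0 - np.clip(profile, 0.0, 1.0)

    rows = []
    for stratum, sub in panel.data.groupby(list(STRATUM_KEYS), sort=False):
        sub = sub.sort_values("quarter").reset_index(drop=True)
        initial = int(sub.loc[0, "pending"] - sub.loc[0, "additions"] + sub.loc[0, "removals"])
        if initial < 0:
            raise BandReconciliationError(
                f"stratum {stratum}: implied initial stock is negative"
            )
        entries = [-1]
        counts = [initial]
        for i, row in sub.iterrows():
            entries.append(i)
            counts.append(int(row["additions"]))
            ent = np.array(entries)
            cnt = np.array(counts, dtype="int64")
            ages = i - ent
            bands = _band_of_age(ages, edges)
            removals = int(row["removals"])
            if removals > cnt.sum():
                raise BandReconciliationError(
                    f"stratum {stratum} quarter {row['quarter']}: removals "
                    f"{removals} exceed referrals on the list ({cnt.sum()})"
                )
            # a cohort that has just spent a full quarter in a band with
            # zero continuation may not survive it: it must resolve now
            prev_bands = _band_of_age(np.maximum(ages - 1, 0), edges)
            forced = (ages >= 1) & (resolve_propensity[prev_bands] >= 1.0)
            n_forced = int(cnt[forced].sum())
            if removals < n_forced:
                raise BandReconciliationError(
                    f"stratum {stratum} quarter {row['quarter']}: the aging "
                    f"profile requires {n_forced} resolutions but the panel "
                    f"records only {removals} removals"
                )
            weights = np.where(forced, 0.0, cnt * resolve_propensity[bands])
            if weights.sum() <= 0 and removals > n_forced:
                raise BandReconciliationError(
                    f"stratum {stratum} quarter {row['quarter']}: "
                    f"{removals - n_forced} removals beyond the forced ones "
                    "but the aging profile resolves nothing"
                )
            removed = _capped_apportion(
                removals - n_forced, weights, np.where(forced, 0, cnt)
            )
            removed = removed + np.where(forced, cnt, 0)
            cnt = cnt - removed
            counts = cnt.tolist()

            if kind == "completed":
                band_counts = np.bincount(bands, weights=removed, minlength=n_bands)
            else:
                band_counts = np.bincount(bands, weights=cnt, minlength=n_bands)
            for b in range(n_bands):
                rows.append(
                    {
                        "quarter": row["quarter"],
                        "elective_type": stratum[0],
                        "hb_code": stratum[1],
                        "specialty": stratum[2],
                        "band": b,
                        "count": int(band_counts[b]),
                    }
                )
    return WaitBandTable(pd.DataFrame(rows), edges=edges, kind=kind)


# ---------------------------------------------------------------------------
# Known-coefficient model frames for estimator studies
# ---------------------------------------------------------------------------


def simulate_varx_frame(
    n_quarters: int = 44,
    *,
    phi: Mapping[int, float] = None,
    beta_additions: float = 1.0,
    beta_removals: float = -1.0,
    equilibrium_pending: float = 100_000.0,
    noise_sd: float = 100.0,
    additions_baseline: float = 100_000.0,
    removals_baseline: float = 100_000.0,
    seasonal_additions: Sequence[float] = (8_000.0, -2_000.0, -10_000.0, 4_000.0),
    seasonal_removals: Sequence[float] = (4_000.0, 6_000.0, -12_000.0, 2_000.0),
    flow_noise_sd: float = 2_000.0,
    start: str = "2013Q1",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a (pending, additions, removals) frame from known dynamics.

    The pending stock follows the autoregression

        pending[t] = c + sum_l phi[l] * pending[t-l]
                       + beta_a * additions[t] + beta_r * removals[t] + eps[t]

    with Gaussian innovations of standard deviation ``noise_sd`` and
    seasonal exogenous flows.  The intercept c is chosen so the stationary
    mean of pending equals ``equilibrium_pending``; presample lags start at
    that mean.  Unlike an accounting panel this series carries its own
    equation noise, so it exercises estimation rather than bookkeeping.
    """
    phi = dict(phi) if phi is not None else {1: 0.5, 4: 0.3}
    if not phi or max(phi) < 1:
        raise ValueError("phi must map positive lags to coefficients")
    rng = np.random.default_rng(seed)
    start_q = as_quarter(start)
    quarters = pd.period_range(start=start_q, periods=n_quarters, freq=start_q.freq)
    qoy = np.array([q.quarter - 1 for q in quarters])

    additions = (
        additions_baseline
        + np.asarray(seasonal_additions)[qoy]
        + rng.normal(0.0, flow_noise_sd, n_quarters)
    )
    removals = (
        removals_baseline
        + np.asarray(seasonal_removals)[qoy]
        + rng.normal(0.0, flow_noise_sd, n_quarters)
    )

    phi_sum = sum(phi.values())
    intercept = equilibrium_pending * (1.0 - phi_sum) - (
        beta_additions * additions_baseline + beta_removals * removals_baseline
    )
    max_lag = max(phi)
    pending = np.empty(n_quarters)
    history = [equilibrium_pending] * max_lag  # most recent last
    eps = rng.normal(0.0, noise_sd, n_quarters)
    for i in range(n_quarters):
        val = intercept + beta_additions * additions[i] + beta_removals * removals[i]
        for lag, coef in phi.items():
            past = pending[i - lag] if i - lag >= 0 else history[i - lag]
            val += coef * past
        pending[i] = val + eps[i]
    return pd.DataFrame(
        {"pending": pending, "additions": additions, "removals": removals},
        index=quarters,
    )


def save_synthetic_dataset(
    directory,
    config: SyntheticConfig,
    panel: WaitlistPanel,
    bands: WaitBandTable | None = None,
) -> dict:
    """Write panel (and optionally bands) as canonical CSV plus a YAML
    sidecar recording every generator parameter and the seed."""
    import pathlib

    import yaml

    from .io_phs import write_panel, write_wait_bands

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"panel": directory / "panel.csv", "config": directory / "config.yaml"}
    write_panel(panel, paths["panel"])
    if bands is not None:
        paths["bands"] = directory / f"wait_bands_{bands.kind}.csv"
        write_wait_bands(bands, paths["bands"])
    cfg = dataclasses.asdict(config)
    cfg["strata"] = [dataclasses.asdict(s) for s in config.strata]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths
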