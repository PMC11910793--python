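"""Canonical containers for quarterly waiting-list data.

The unit of analysis is the quarterly aggregate per stratum, where a stratum
is a triple (elective type, health board, specialty).  Two containers cover
everything downstream code needs:

``WaitlistPanel``
    The stock-flow history: referrals *added* to the list, referrals
    *removed* from it (realised throughput -- patients seen, transferred,
    no longer requiring treatment, or deceased), and the *pending* stock at
    each quarter end.  The accounting identity

        pending[t] = pending[t-1] + additions[t] - removals[t]

    holds exactly for synthetic data; for real data the reconciliation
    residual is computed and reported, never silently repaired.

``WaitBandTable``
    Counts of referrals by wait-duration band (e.g. 0-12 weeks,
    13-52 weeks, >52 weeks) per quarter, either for referrals still waiting
    (``kind="ongoing"``) or for referrals resolved in the quarter
    (``kind="completed"``).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

QUARTER_FREQ = "Q-DEC"

STRATUM_KEYS = ("elective_type", "hb_code", "specialty")
PANEL_COLUMNS = ("quarter", *STRATUM_KEYS, "additions", "removals", "pending")
BAND_COLUMNS = ("quarter", *STRATUM_KEYS, "band", "count")

#: labels used when a stratum dimension has been aggregated away
AGGREGATE_LABELS = {"elective_type": "all", "hb_code": "Scotland", "specialty": "all"}


class PanelValidationError(ValueError):
    """Raised when input data violates the panel contract."""


class BandReconciliationError(ValueError):
    """Raised when band counts cannot be reconciled with panel totals."""


def as_quarter(value) -> pd.Period:
    """Coerce a label ('2019Q4', a date, a Period) to a calendar quarter."""
    return pd.Period(value, freq=QUARTER_FREQ)


def _coerce_quarters(col: pd.Series) -> pd.Series:
    if isinstance(col.dtype, pd.PeriodDtype):
        if col.dtype.freq.freqstr.startswith("Q"):
            return col
        return col.dt.asfreq(QUARTER_FREQ)
    return col.map(as_quarter)


def _require_integer_counts(frame: pd.DataFrame, cols: Sequence[str]) -> None:
    for c in cols:
        vals = frame[c].to_numpy()
        if not np.isfinite(vals).all():
            raise PanelValidationError(f"column {c!r} contains non-finite values")
        if np.any(vals < 0):
            bad = frame.loc[frame[c] < 0, "quarter"].iloc[0]
            raise PanelValidationError(f"negative {c!r} count at quarter {bad}")
        if np.any(vals != np.round(vals)):
            raise PanelValidationError(
                f"column {c!r} contains fractional values; counts must be integers"
            )


class WaitlistPanel:
    """Quarterly stock-flow series per stratum.

    Parameters
    ----------
    data:
        Tidy frame with columns ``quarter, elective_type, hb_code,
        specialty, additions, removals, pending``.
    strict_conservation:
        If True (synthetic data), the accounting identity must hold exactly
        in every stratum and quarter, otherwise construction fails.  If
        False (real data), residuals above ``conservation_tol`` (as a
        fraction of the pending stock) trigger a warning only.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        strict_conservation: bool = False,
        conservation_tol: float = 0.01,
        validate: bool = True,
    ):
        missing = [c for c in PANEL_COLUMNS if c not in data.columns]
        if missing:
            raise PanelValidationError(f"panel frame missing columns: {missing}")
        data = data.loc[:, list(PANEL_COLUMNS)].copy()
        data["quarter"] = _coerce_quarters(data["quarter"])
        data = data.sort_values([*STRATUM_KEYS, "quarter"]).reset_index(drop=True)
        for c in ("additions", "removals", "pending"):
            data[c] = pd.to_numeric(data[c])
        self.data = data
        self.strict_conservation = strict_conservation
        self.conservation_tol = conservation_tol
        if validate:
            self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        _require_integer_counts(df, ("additions", "removals", "pending"))
        for c in ("additions", "removals", "pending"):
            df[c] = df[c].astype("int64")

        dup = df.duplicated(subset=["quarter", *STRATUM_KEYS], keep=False)
        if dup.any():
            q = df.loc[dup, "quarter"].iloc[0]
            raise PanelValidationError(
                f"duplicate (quarter, stratum) rows, e.g. at quarter {q}"
            )
        for stratum, sub in df.groupby(list(STRATUM_KEYS), sort=False):
            quarters = sub["quarter"].to_numpy()
            steps = np.array(
                [(b - a).n for a, b in zip(quarters[:-1], quarters[1:])], dtype=int
            )
            if np.any(steps != 1):
                raise PanelValidationError(
                    f"quarters not contiguous/increasing for stratum {stratum}"
                )
        resid = self.conservation_residuals()
        if self.strict_conservation:
            if (resid["residual"] != 0).any():
                bad = resid.loc[resid["residual"] != 0].iloc[0]
                raise PanelValidationError(
                    "stock-flow conservation violated at quarter "
                    f"{bad['quarter']} (residual {bad['residual']})"
                )
        else:
            scale = resid["pending"].clip(lower=1)
            frac = resid["residual"].abs() / scale
            if (frac > self.conservation_tol).any():
                n = int((frac > self.conservation_tol).sum())
                worst = frac.max()
                warnings.warn(
                    f"{n} quarter(s) exceed the conservation residual tolerance "
                    f"({self.conservation_tol:.1%}); worst relative residual "
                    f"{worst:.2%}. Residuals are reported, not repaired.",
                    stacklevel=3,
                )

    # -- basic views ---------------------------------------------------

    @property
    def quarters(self) -> pd.PeriodIndex:
        return pd.PeriodIndex(sorted(self.data["quarter"].unique()), freq=QUARTER_FREQ)

    def strata(self) -> list[tuple[str, str, str]]:
        return [
            tuple(t)
            for t in self.data[list(STRATUM_KEYS)].drop_duplicates().itertuples(index=False)
        ]

    def subset(self, **keys: str) -> "WaitlistPanel":
        """Restrict to strata matching the given key values."""
        bad = set(keys) - set(STRATUM_KEYS)
        if bad:
            raise KeyError(f"unknown stratum keys: {sorted(bad)}")
        mask = pd.Series(True, index=self.data.index)
        for k, v in keys.items():
            mask &= self.data[k] == v
        sub = self.data.loc[mask]
        if sub.empty:
            raise PanelValidationError(f"no rows match stratum selection {keys}")
        return WaitlistPanel(
            sub,
            strict_conservation=self.strict_conservation,
            conservation_tol=self.conservation_tol,
        )

    def conservation_residuals(self) -> pd.DataFrame:
        """Per stratum/quarter residual pending.diff - (additions - removals).

        The first quarter of each stratum has no predecessor and is reported
        with residual 0.
        """
        parts = []
        for stratum, sub in self.data.groupby(list(STRATUM_KEYS), sort=False):
            sub = sub.sort_values("quarter")
            resid = sub["pending"].diff() - (sub["additions"] - sub["removals"])
            out = sub[["quarter", *STRATUM_KEYS, "pending"]].copy()
            out["residual"] = resid.fillna(0).astype("int64")
            parts.append(out)
        return pd.concat(parts, ignore_index=True)

    def aggregate(self, by: Sequence[str] = ()) -> "WaitlistPanel":
        """Sum counts over all stratum keys not listed in ``by``.

        Collapsed dimensions get the conventional aggregate labels
        ('all' / 'Scotland' / 'all').  Summation preserves the accounting
        identity, so strictness carries over.
        """
        by = list(by)
        bad = set(by) - set(STRATUM_KEYS)
        if bad:
            raise KeyError(f"unknown stratum keys: {sorted(bad)}")
        grouped = (
            self.data.groupby(["quarter", *by], sort=True, observed=True)[
                ["additions", "removals", "pending"]
            ]
            .sum()
            .reset_index()
        )
        for k in STRATUM_KEYS:
            if k not in by:
                grouped[k] = AGGREGATE_LABELS[k]
        return WaitlistPanel(
            grouped,
            strict_conservation=self.strict_conservation,
            conservation_tol=self.conservation_tol,
        )

    def series(self, measure: str, **stratum: str) -> pd.Series:
        """Quarterly series of one measure, aggregated over all strata.

        Keyword arguments restrict to matching strata before aggregation.
        """
        if measure not in ("additions", "removals", "pending"):
            raise KeyError(f"unknown measure {measure!r}")
        panel = self.subset(**stratum) if stratum else self
        agg = panel.data.groupby("quarter", sort=True)[measure].sum()
        agg.index = pd.PeriodIndex(agg.index, freq=QUARTER_FREQ)
        return agg.rename(measure)

    def to_model_frame(self, split_pending_by_type: bool = False) -> pd.DataFrame:
        """Wide frame for model fitting, indexed by quarter.

        Default columns: ``pending, additions, removals`` (all strata
        summed).  With ``split_pending_by_type`` the pending stock is
        returned per elective type (``pending_<type>``) while the flows
        remain aggregated, supporting a joint two-series endogenous block.
        """
        frame = pd.DataFrame(
            {
                "pending": self.series("pending"),
                "additions": self.series("additions"),
                "removals": self.series("removals"),
            }
        )
        if split_pending_by_type:
            types = sorted(self.data["elective_type"].unique())
            if len(types) < 2:
                raise PanelValidationError(
                    "split_pending_by_type requires at least two elective types"
                )
            for t in types:
                frame[f"pending_{t}"] = self.series("pending", elective_type=t)
            frame = frame.drop(columns="pending")
        return frame

    def __len__(self) -> int:
        return len(self.quarters)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        q = self.quarters
        return (
            f"WaitlistPanel({len(q)} quarters {q[0]}..{q[-1]}, "
            f"{len(self.strata())} strata)"
        )


class WaitBandTable:
    """Counts of referrals by wait-duration band.

    Bands are defined by ``edges`` in weeks: edges ``(12, 52)`` give the
    three bands 0-12, 13-52 and >52 weeks.  Bands are ordered, contiguous
    and exhaustive; the final band is open-ended.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        edges: Sequence[float] = (12, 52),
        kind: str = "ongoing",
        validate: bool = True,
    ):
        if kind not in ("ongoing", "completed"):
            raise ValueError("kind must be 'ongoing' or 'completed'")
        edges = tuple(float(e) for e in edges)
        if list(edges) != sorted(edges) or len(set(edges)) != len(edges) or not edges:
            raise ValueError("band edges must be strictly increasing and non-empty")
        missing = [c for c in BAND_COLUMNS if c not in data.columns]
        if missing:
            raise PanelValidationError(f"band frame missing columns: {missing}")
        data = data.loc[:, list(BAND_COLUMNS)].copy()
        data["quarter"] = _coerce_quarters(data["quarter"])
        data["band"] = data["band"].astype(int)
        self.data = data.sort_values([*STRATUM_KEYS, "quarter", "band"]).reset_index(
            drop=True
        )
        self.edges = edges
        self.kind = kind
        if validate:
            self._validate()

    @property
    def n_bands(self) -> int:
        return len(self.edges) + 1

    def band_labels(self) -> list[str]:
        labels = [f"0-{self.edges[0]:g}"]
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            labels.append(f"{lo:g}-{hi:g}")
        labels.append(f">{self.edges[-1]:g}")
        return labels

    def _validate(self) -> None:
        df = self.data
        _require_integer_counts(df, ("count",))
        df["count"] = df["count"].astype("int64")
        if df["band"].min() < 0 or df["band"].max() >= self.n_bands:
            raise PanelValidationError(
                f"band index out of range 0..{self.n_bands - 1}"
            )
        dup = df.duplicated(subset=["quarter", *STRATUM_KEYS, "band"], keep=False)
        if dup.any():
            q = df.loc[dup, "quarter"].iloc[0]
            raise PanelValidationError(f"duplicate band rows at quarter {q}")

    def totals(self, **stratum: str) -> pd.Series:
        df = self.data
        for k, v in stratum.items():
            df = df[df[k] == v]
        tot = df.groupby("quarter", sort=True)["count"].sum()
        tot.index = pd.PeriodIndex(tot.index, freq=QUARTER_FREQ)
        return tot

    def counts(self, quarter, **stratum: str) -> np.ndarray:
        """Per-band counts for one quarter (aggregated over strata)."""
        q = as_quarter(quarter)
        df = self.data[self.data["quarter"] == q]
        for k, v in stratum.items():
            df = df[df[k] == v]
        if df.empty:
            raise KeyError(f"no band rows for quarter {q}")
        out = np.zeros(self.n_bands, dtype="int64")
        agg = df.groupby("band")["count"].sum()
        out[agg.index.to_numpy()] = agg.to_numpy()
        return out

    def reconcile(self, panel: WaitlistPanel, tol: float = 0.0) -> pd.DataFrame:
        """Compare per-quarter band sums with the matching panel totals.

        For ``kind='ongoing'`` bands must partition the pending stock; for
        ``kind='completed'`` they must partition the removals.  Residuals
        above ``tol`` (fraction of the panel total) trigger a warning; the
        residual frame is always returned, never applied.
        """
        measure = "pending" if self.kind == "ongoing" else "removals"
        panel_tot = panel.series(measure)
        band_tot = self.totals()
        idx = band_tot.index.intersection(panel_tot.index)
        resid = pd.DataFrame(
            {
                "quarter": idx,
                "band_total": band_tot.loc[idx].to_numpy(),
                "panel_total": panel_tot.loc[idx].to_numpy(),
            }
        )
        resid["residual"] = resid["band_total"] - resid["panel_total"]
        scale = resid["panel_total"].clip(lower=1)
        bad = resid["residual"].abs() / scale > tol
        if bad.any():
            first = resid.loc[bad].iloc[0]
            warnings.warn(
                f"band totals disagree with panel {measure} in {int(bad.sum())} "
                f"quarter(s), e.g. {first['quarter']}: band sum "
                f"{first['band_total']} vs panel {first['panel_total']}",
                stacklevel=2,
            )
        return resid

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WaitBandTable(kind={self.kind!r}, bands={self.band_labels()}, "
            f"{self.data['quarter'].nunique()} quarters)"
        )
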