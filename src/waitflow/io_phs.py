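"""Read and write waiting-list CSVs in the Public Health Scotland dialect.

Public Health Scotland publishes the quarterly "Stage of Treatment" open
data as plain CSVs whose column vocabulary has drifted across releases, so
no single dialect is hard-coded: a :class:`ColumnSchema` maps source column
names (and, where needed, source values) onto the canonical fields, and can
be loaded from a YAML config.  The canonical on-disk form, which the
synthetic generator also writes, is

    quarter_end_date, elective_type, hb_code, specialty,
    additions, removals, pending

with one row per (quarter, stratum), quarters labelled by their calendar
end date (so "end of 2019" is the 2019Q4 row, snapshot December 31).  Band
tables add ``kind, band_low_weeks, band_high_weeks, count`` in place of the
three count columns.  Read followed by write is the identity on canonical
files.  All counts are integers; fractional inputs are rejected, not
rounded.  Conservation problems are reported (warned), never repaired.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .panel import (
    QUARTER_FREQ,
    STRATUM_KEYS,
    PanelValidationError,
    WaitBandTable,
    WaitlistPanel,
)

CANONICAL_PANEL_COLUMNS = (
    "quarter_end_date",
    "elective_type",
    "hb_code",
    "specialty",
    "additions",
    "removals",
    "pending",
)
CANONICAL_BAND_COLUMNS = (
    "quarter_end_date",
    "elective_type",
    "hb_code",
    "specialty",
    "kind",
    "band_low_weeks",
    "band_high_weeks",
    "count",
)


@dataclass(frozen=True)
class ColumnSchema:
    """Mapping from a source CSV dialect to canonical fields.

    ``columns`` maps canonical names to source column names; ``value_maps``
    optionally recodes source values (e.g. PHS board codes to display
    names) per canonical column.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    value_maps: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path) -> "ColumnSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            columns=raw.get("columns", {}), value_maps=raw.get("value_maps", {})
        )


CANONICAL_SCHEMA = ColumnSchema()


def _as_paths(paths) -> list[Path]:
    if isinstance(paths, (str, Path)):
        paths = [paths]
    out = [Path(p) for p in paths]
    for p in out:
        if not p.exists():
            raise FileNotFoundError(p)
    return out


def _load(paths, schema: ColumnSchema, needed: Sequence[str]) -> pd.DataFrame:
    frames = []
    for path in _as_paths(paths):
        df = pd.read_csv(path)
        rename = {}
        missing = []
        for canonical in needed:
            src = schema.source_name(canonical)
            if src not in df.columns:
                missing.append(src)
            else:
                rename[src] = canonical
        if missing:
            raise PanelValidationError(
                f"{path}: missing required column(s) {missing} "
                f"(have: {list(df.columns)})"
            )
        df = df.rename(columns=rename).loc[:, list(needed)]
        for canonical, mapping in schema.value_maps.items():
            if canonical in df.columns:
                df[canonical] = df[canonical].map(lambda v: mapping.get(v, v))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _parse_quarters(dates: pd.Series, source: str) -> pd.Series:
    parsed = pd.to_datetime(dates, format="mixed", errors="coerce")
    if parsed.isna().any():
        bad = dates[parsed.isna()].iloc[0]
        raise PanelValidationError(f"{source}: unparseable quarter-end date {bad!r}")
    return parsed.dt.to_period(QUARTER_FREQ)


def read_panel(
    paths,
    schema: ColumnSchema | str | Path | None = None,
    *,
    conservation_tol: float = 0.01,
) -> WaitlistPanel:
    """Read one or more stock-flow CSVs into a validated panel.

    Duplicate (quarter, stratum) rows, missing columns, unparseable dates,
    fractional or negative counts are rejected with diagnostics naming the
    offending row or quarter; conservation residuals above
    ``conservation_tol`` (fraction of pending) warn but are kept as data.
    """
    if schema is None:
        schema = CANONICAL_SCHEMA
    elif not isinstance(schema, ColumnSchema):
        schema = ColumnSchema.from_yaml(schema)
    df = _load(paths, schema, CANONICAL_PANEL_COLUMNS)
    df["quarter"] = _parse_quarters(df["quarter_end_date"], "panel")
    df = df.drop(columns="quarter_end_date")
    return WaitlistPanel(df, conservation_tol=conservation_tol)


def write_panel(panel: WaitlistPanel, path) -> Path:
    """Write a panel as canonical CSV (fixed column order)."""
    out = panel.data.copy()
    out["quarter_end_date"] = out["quarter"].map(
        lambda p: p.end_time.date().isoformat()
    )
    out = out.loc[:, list(CANONICAL_PANEL_COLUMNS)]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_wait_bands(
    paths,
    schema: ColumnSchema | str | Path | None = None,
    *,
    panel: WaitlistPanel | None = None,
    reconcile_tol: float = 0.0,
) -> WaitBandTable:
    """Read band-count CSVs into a validated :class:`WaitBandTable`.

    Bands must be ordered, contiguous and exhaustive with an open-ended
    final band; if ``panel`` is given, band sums are reconciled against the
    matching panel totals (residuals warned, never applied).
    """
    if schema is None:
        schema = CANONICAL_SCHEMA
    elif not isinstance(schema, ColumnSchema):
        schema = ColumnSchema.from_yaml(schema)
    df = _load(paths, schema, CANONICAL_BAND_COLUMNS)
    df["quarter"] = _parse_quarters(df["quarter_end_date"], "wait bands")

    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise PanelValidationError(f"band file mixes kinds {sorted(kinds)}")
    kind = str(kinds[0])

    lows = pd.to_numeric(df["band_low_weeks"]).to_numpy(dtype=float)
    highs = pd.to_numeric(df["band_high_weeks"], errors="coerce").to_numpy(dtype=float)
    highs = np.where(np.isnan(highs), np.inf, highs)  # inf = open-ended
    pairs = sorted({(lo, hi) for lo, hi in zip(lows, highs)}, key=lambda p: p[0])
    edges = []
    expected_low = 0.0
    for i, (lo, hi) in enumerate(pairs):
        if lo != expected_low:
            raise PanelValidationError(
                f"bands are not contiguous: band starting at {lo} follows "
                f"edge {expected_low}"
            )
        if i == len(pairs) - 1:
            if np.isfinite(hi):
                raise PanelValidationError("final band must be open-ended")
        else:
            if not np.isfinite(hi):
                raise PanelValidationError("only the final band may be open-ended")
            edges.append(float(hi))
            expected_low = float(hi)
    band_index = {pair: i for i, pair in enumerate(pairs)}
    df["band"] = [band_index[(lo, hi)] for lo, hi in zip(lows, highs)]
    table = WaitBandTable(df, edges=edges, kind=kind)
    if panel is not None:
        table.reconcile(panel, tol=reconcile_tol)
    return table


def write_wait_bands(table: WaitBandTable, path) -> Path:
    """Write a band table as canonical CSV."""
    edges = table.edges
    lows = [0.0, *edges]
    highs = [*edges, np.nan]
    out = table.data.copy()
    out["quarter_end_date"] = out["quarter"].map(
        lambda p: p.end_time.date().isoformat()
    )
    out["kind"] = table.kind
    out["band_low_weeks"] = out["band"].map(lambda b: lows[b])
    out["band_high_weeks"] = out["band"].map(lambda b: highs[b])
    out = out.loc[:, list(CANONICAL_BAND_COLUMNS)]
    path = Path(path)
    out.to_csv(path, index=False)
    return path
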