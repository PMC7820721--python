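"""Run cleaning, distance normalization, situation vectors, weekly matrix.

The stages here turn raw run records into the two analysis inputs:

* **weighted transactions** — per run, the 29 categorical (feature, value)
  items plus a weight in [-1, 1], the run distance normalized by the user's
  personal statistics::

      w = (y - average(y_user)) / (max(y_user) - min(y_user))

  so a run at the user's mean distance maps to exactly 0, the personal best
  to at most +1 and the personal worst to at least -1;

* **the weekly activity matrix** — per user, run counts over the most active
  window of 52 consecutive ISO weeks of their history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    ALL_FEATURES,
    HOUR_BINS,
    HUMIDITY_TYPES,
    MONTHS,
    WEATHER_TYPES,
    WEEKDAYS,
    WIND_TYPES,
    temperature_bin,
)
from .geo_context import GEO_FEATURES, BinningScheme, GeoContextStack

logger = logging.getLogger(__name__)

MIN_DISTANCE_M = 100.0
MIN_RUNS_PER_USER = 10

_REQUIRED = ["activity_id", "user_id", "total_distance_m", "start_timestamp", "start_x", "start_y"]


def clean_runs(runs: pd.DataFrame, stack: GeoContextStack | None = None) -> tuple[pd.DataFrame, dict]:
    """Remove invalid runs; returns (retained, drop log).

    Dropped are runs with missing or unparseable fields, weather/wind/humidity
    values outside the fixed vocabularies, total distance below 100 m, and —
    when a :class:`GeoContextStack` is given — start points outside the raster
    or outside every neighborhood polygon (no geographic context). Cleaning is
    idempotent.
    """
    df = runs.copy()
    drops: dict[str, int] = {}

    def drop(mask: np.ndarray, reason: str):
        nonlocal df
        n = int(mask.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
            df = df[~mask]

    df["start_timestamp"] = pd.to_datetime(df["start_timestamp"], errors="coerce")
    missing = df[_REQUIRED].isna().any(axis=1)
    for col in ["total_distance_m", "temperature_c", "start_x", "start_y"]:
        missing |= ~np.isfinite(pd.to_numeric(df[col], errors="coerce").fillna(np.nan))
    drop(missing.to_numpy(), "missing_or_unparseable")

    bad_cat = (
        ~df["weather_type"].isin(WEATHER_TYPES)
        | ~df["wind_type"].isin(WIND_TYPES)
        | ~df["humidity_type"].isin(HUMIDITY_TYPES)
    )
    drop(bad_cat.to_numpy(), "invalid_category")

    drop((df["total_distance_m"] < MIN_DISTANCE_M).to_numpy(), "distance_below_100m")

    if stack is not None:
        rows, cols, inside = stack.landuse.grid.cell_of(df["start_x"].to_numpy(), df["start_y"].to_numpy())
        drop(~inside, "outside_raster")
        rows, cols, _ = stack.landuse.grid.cell_of(df["start_x"].to_numpy(), df["start_y"].to_numpy())
        demo = next(iter(stack.demographics.values()))
        drop(np.isnan(demo[rows, cols]), "no_neighborhood_context")

    for reason, n in drops.items():
        logger.info("clean_runs: dropped %d runs (%s)", n, reason)
    return df.reset_index(drop=True), drops


def filter_sparse_users(runs: pd.DataFrame, min_runs: int = MIN_RUNS_PER_USER) -> pd.DataFrame:
    """Drop all runs of users with fewer than ``min_runs`` retained runs."""
    counts = runs.groupby("user_id")["activity_id"].transform("size")
    return runs[counts >= min_runs].reset_index(drop=True)


def user_distance_stats(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-user min / average / max of total distance over retained runs."""
    g = runs.groupby("user_id")["total_distance_m"]
    stats = g.agg(dist_min="min", dist_avg="mean", dist_max="max")
    return stats


def normalize_distance(runs: pd.DataFrame) -> pd.Series:
    """Per-run normalized distance weight in [-1, 1].

    ``(y - average) / (max - min)`` over the user's retained runs; users whose
    runs are all identical (max = min) get weight 0 by convention.
    """
    stats = user_distance_stats(runs)
    merged = runs[["user_id", "total_distance_m"]].join(stats, on="user_id")
    span = merged["dist_max"] - merged["dist_min"]
    w = (merged["total_distance_m"] - merged["dist_avg"]).where(span > 0, 0.0) / span.replace(0.0, 1.0)
    return w.rename("weight")


@dataclass
class WeeklyActivityMatrix:
    """Users x 52 weekly run counts (most active 52-ISO-week window)."""

    user_ids: np.ndarray
    counts: np.ndarray  # (n_users, 52) int

    def __post_init__(self):
        self.user_ids = np.asarray(self.user_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 52:
            raise ValueError("weekly matrix must have exactly 52 columns")
        if (self.counts < 0).any():
            raise ValueError("weekly counts must be non-negative")

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    def annual_run_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[f"w{i + 1}" for i in range(52)])
        df.insert(0, "user_id", self.user_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeeklyActivityMatrix":
        df = pd.read_csv(path)
        return cls(df["user_id"].to_numpy(), df[[f"w{i + 1}" for i in range(52)]].to_numpy())


def weekly_matrix(runs: pd.DataFrame) -> WeeklyActivityMatrix:
    """Build the weekly activity matrix from retained runs.

    Per user, run counts are aggregated on that user's own ISO-week axis (from
    their first to their last running week), the 52-consecutive-week window
    with the most runs is selected (ties broken by the earliest window start),
    and histories shorter than 52 weeks are zero-padded on the right.
    """
    ts = pd.to_datetime(runs["start_timestamp"])
    iso = ts.dt.isocalendar()
    # Monday of the ISO week, as an absolute week index
    monday = ts.dt.normalize() - pd.to_timedelta(iso["day"] - 1, unit="D")
    week_idx = (monday - pd.Timestamp("2000-01-03")).dt.days // 7  # anchor: a Monday
    df = pd.DataFrame({"user_id": runs["user_id"].to_numpy(), "week": week_idx.to_numpy()})

    user_ids = []
    rows = []
    for uid, grp in df.groupby("user_id", sort=True):
        w = grp["week"].to_numpy()
        lo = int(w.min())
        axis_len = max(52, int(w.max()) - lo + 1)
        counts = np.bincount(w - lo, minlength=axis_len)
        sums = np.convolve(counts, np.ones(52, dtype=int), mode="valid")
        start = int(np.argmax(sums))  # argmax returns the first (earliest) maximum
        user_ids.append(uid)
        rows.append(counts[start : start + 52])
    return WeeklyActivityMatrix(np.asarray(user_ids), np.asarray(rows, dtype=int))


def _temporal_weather_columns(runs: pd.DataFrame) -> pd.DataFrame:
    ts = pd.to_datetime(runs["start_timestamp"])
    hour = np.asarray(HOUR_BINS, dtype=object)[ts.dt.hour.to_numpy() // 3]
    weekday = np.asarray(WEEKDAYS, dtype=object)[ts.dt.weekday.to_numpy()]
    month = np.asarray(MONTHS, dtype=object)[ts.dt.month.to_numpy() - 1]
    temp = np.array([temperature_bin(t) for t in runs["temperature_c"].to_numpy()], dtype=object)
    return pd.DataFrame(
        {
            "hour": hour,
            "weekday": weekday,
            "month": month,
            "temperature": temp,
            "weather": runs["weather_type"].to_numpy(),
            "wind": runs["wind_type"].to_numpy(),
            "humidity": runs["humidity_type"].to_numpy(),
        }
    )


def build_transactions(
    runs: pd.DataFrame, stack: GeoContextStack, bins: BinningScheme
) -> pd.DataFrame:
    """Weighted transactions: tid, user_id, weight, and the 29 item columns.

    ``runs`` must already be cleaned and sparse-filtered; weights come from
    :func:`normalize_distance` over exactly these runs.
    """
    out = pd.DataFrame(
        {
            "tid": runs["activity_id"].to_numpy(),
            "user_id": runs["user_id"].to_numpy(),
            "weight": normalize_distance(runs).to_numpy(),
        }
    )
    tw = _temporal_weather_columns(runs)
    for col in tw.columns:
        out[col] = tw[col].to_numpy()

    rows, cols, inside = stack.landuse.grid.cell_of(runs["start_x"].to_numpy(), runs["start_y"].to_numpy())
    if not inside.all():
        raise ValueError("build_transactions requires cleaned runs inside the raster")
    geo = stack.geo_values_at(rows, cols)
    for f in GEO_FEATURES:
        vals = geo[f].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing geographic context for feature {f}; clean runs first")
        out[f] = bins.bin_geo_values(f, vals)

    assert list(out.columns[3:]) == list(ALL_FEATURES)
    return out


def extract_features(record, stack: GeoContextStack, bins: BinningScheme) -> dict[str, str]:
    """The 29-item situation vector of a single cleaned run record.

    ``record`` is a mapping (or Series) with the run-table fields. Returns an
    ordered feature -> category dict of length 29.
    """
    one = pd.DataFrame([dict(record)])
    one["activity_id"] = one.get("activity_id", 0)
    one["user_id"] = one.get("user_id", 0)
    tx = build_transactions(one, stack, bins)
    return {f: tx.iloc[0][f] for f in ALL_FEATURES}


def write_transactions_csv(path: str | Path, transactions: pd.DataFrame) -> None:
    transactions.to_csv(path, index=False)


def read_transactions_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
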