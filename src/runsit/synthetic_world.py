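"""Synthetic landscapes, runner populations and run histories.

The generator emulates the structure of a 4-year mobile-fitness dataset joined
with landuse and neighborhood statistics, with *known-by-construction* ground
truth so every downstream stage (context enrichment, normalization, clustering,
situation mining) can be validated:

* a landuse raster grown as contiguous patches over the 9 classes, plus a
  rectangular neighborhood tiling with 4 demographic attributes;
* two runner archetypes — *sporadic* users averaging ~34 runs/year packed into
  a sub-period of the year, and *regular* users averaging ~94 runs/year spread
  consistently — with per-user baseline distances;
* run records whose distance is baseline + planted additive situation effects
  (scaled by the archetype's situation sensitivity) + Gaussian noise, with
  seasonally structured weather and diurnal/weekly start-time preferences.

Everything is deterministic per seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .features import (
    FEATURE_CATEGORY,
    HUMIDITY_TYPES,
    LANDUSE_CLASSES,
    WEATHER_TYPES,
    WIND_TYPES,
    temperature_bin,
    temporal_items,
)
from .geo_context import BinningScheme, GeoContextStack, Grid, LanduseRaster

RUN_CSV_COLUMNS = [
    "activity_id",
    "user_id",
    "total_distance_m",
    "start_timestamp",
    "start_x",
    "start_y",
    "weather_type",
    "temperature_c",
    "wind_type",
    "humidity_type",
]

#: Default class mix of the synthetic landscape (fractions of seeded patches).
DEFAULT_CLASS_MIX = {
    "parks": 0.06,
    "sports": 0.04,
    "recreation": 0.05,
    "forest": 0.10,
    "water": 0.08,
    "agriculture": 0.30,
    "traffic": 0.08,
    "residential": 0.22,
    "cbd": 0.07,
}

#: Monthly mean temperature (C), a temperate maritime climate.
MONTHLY_TEMP_MEAN = (3.0, 3.5, 6.0, 9.0, 13.0, 16.0, 18.0, 18.0, 15.0, 11.0, 7.0, 4.0)

# Season -> weather type probabilities (winter = Dec-Feb, etc.).
_SEASON_OF_MONTH = (0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 0)
_WEATHER_P = {
    0: (0.10, 0.15, 0.30, 0.20, 0.10, 0.01, 0.06, 0.02, 0.06),
    1: (0.20, 0.22, 0.25, 0.15, 0.08, 0.02, 0.01, 0.01, 0.06),
    2: (0.30, 0.25, 0.18, 0.12, 0.06, 0.04, 0.00, 0.01, 0.04),
    3: (0.18, 0.20, 0.28, 0.18, 0.08, 0.02, 0.00, 0.01, 0.05),
}
_WIND_P = (0.15, 0.40, 0.30, 0.13, 0.02)
_HUMIDITY_P = (0.25, 0.50, 0.25)


@dataclass(frozen=True)
class RunnerArchetypeSpec:
    """Parameters of one runner archetype.

    ``spread`` is either ``"consistent"`` (runs placed in any week of the
    year) or ``"bursty"`` (each user runs within a contiguous sub-period of
    the year). ``situation_sensitivity`` multiplies every planted effect delta
    for users of this archetype.
    """

    label: str
    annual_run_count_mean: float
    spread: str = "consistent"
    active_weeks_min: int = 10
    active_weeks_max: int = 30
    baseline_distance_mean: float = 6000.0
    baseline_distance_sd: float = 1500.0
    situation_sensitivity: float = 1.0
    #: preference weights over the eight 3-hour start slots [0,3) .. [21,24)
    diurnal_prefs: tuple = (0.01, 0.01, 0.10, 0.28, 0.16, 0.14, 0.22, 0.08)
    #: preference weights over weekdays Monday..Sunday
    weekday_prefs: tuple = (0.12, 0.13, 0.14, 0.12, 0.11, 0.16, 0.22)

    def __post_init__(self):
        if self.annual_run_count_mean <= 0:
            raise ValueError("annual_run_count_mean must be positive")
        if self.situation_sensitivity < 0:
            raise ValueError("situation_sensitivity must be >= 0")
        if self.spread not in ("consistent", "bursty"):
            raise ValueError("spread must be 'consistent' or 'bursty'")


#: Study-condition archetypes: sporadic ~34 runs/yr in a sub-period of the
#: year with high situation sensitivity, regular ~94 runs/yr spread over the
#: year with low sensitivity.
SPORADIC = RunnerArchetypeSpec(
    label="sporadic",
    annual_run_count_mean=34.0,
    spread="bursty",
    situation_sensitivity=2.0,
)
REGULAR = RunnerArchetypeSpec(
    label="regular",
    annual_run_count_mean=94.0,
    spread="consistent",
    situation_sensitivity=0.5,
)
DEFAULT_ARCHETYPES = {"sporadic": SPORADIC, "regular": REGULAR}
DEFAULT_FRACTIONS = {"sporadic": 0.8, "regular": 0.2}


@dataclass(frozen=True)
class UserProfile:
    user_id: int
    archetype: str
    annual_runs: float
    baseline_m: float
    sensitivity: float
    active_week_start: int | None = None  # bursty archetypes only
    active_week_len: int | None = None
    diurnal_prefs: tuple = RunnerArchetypeSpec.diurnal_prefs
    weekday_prefs: tuple = RunnerArchetypeSpec.weekday_prefs


@dataclass(frozen=True)
class SituationEffect:
    """An additive distance shift planted on runs matching a situation.

    ``items`` maps feature name -> category label (e.g. ``{"weekday":
    "Sunday", "hour": "[09,12)"}``); a run matches when its situation vector
    contains every item. ``delta_m`` is added to the run distance, scaled by
    the user's archetype sensitivity.
    """

    items: dict
    delta_m: float

    def __post_init__(self):
        if not np.isfinite(self.delta_m):
            raise ValueError("delta must be finite")
        for f in self.items:
            if f not in FEATURE_CATEGORY:
                raise ValueError(f"unknown feature {f!r} in effect")

    @property
    def features(self) -> tuple:
        return tuple(self.items)


def make_landscape(
    seed: int,
    width_cells: int,
    height_cells: int,
    class_mix: dict | None = None,
    cell_size: float = 100.0,
    n_neighborhoods_side: int = 4,
):
    """Grow a patchy landuse raster and tile it with neighborhood polygons.

    Patches are Voronoi regions of seeded points labeled by ``class_mix``, so
    classes form contiguous regions (spatial autocorrelation) rather than
    i.i.d. noise. Every class with positive mix receives at least one seed
    point. Neighborhood demographics correlate with residential coverage;
    purely non-residential neighborhoods get density 0 so the zero demographic
    category is populated.
    """
    if width_cells < 10 or height_cells < 10:
        raise ValueError("landscape must be at least 10x10 cells")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    unknown = set(mix) - set(LANDUSE_CLASSES)
    if unknown:
        raise ValueError(f"unknown landuse classes in mix: {sorted(unknown)}")
    probs = np.array([mix.get(c, 0.0) for c in LANDUSE_CLASSES], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("class_mix must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    grid = Grid(origin=(0.0, 0.0), cell_size=float(cell_size), width=width_cells, height=height_cells)

    positive = [i for i, p in enumerate(probs) if p > 0]
    n_seeds = max(len(positive), width_cells * height_cells // 40)
    labels = list(positive)
    labels += list(rng.choice(len(LANDUSE_CLASSES), size=n_seeds - len(positive), p=probs))
    seed_rows = rng.integers(0, height_cells, size=n_seeds)
    seed_cols = rng.integers(0, width_cells, size=n_seeds)

    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([seed_rows, seed_cols]))
    rr, cc = np.meshgrid(np.arange(height_cells), np.arange(width_cells), indexing="ij")
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    codes = np.asarray(labels)[nearest].reshape(height_cells, width_cells) + 1
    # Voronoi ties can eat a single-seed class; re-stamp forced seeds.
    for i in positive:
        codes[seed_rows[i], seed_cols[i]] = i + 1
    raster = LanduseRaster(grid=grid, classes=codes)

    neighborhoods = _make_neighborhoods(rng, raster, n_neighborhoods_side)
    return raster, neighborhoods


def _make_neighborhoods(rng, raster: LanduseRaster, k: int) -> pd.DataFrame:
    """Tile the extent into a k x k jittered rectangular grid of polygons."""
    xmin, ymin, xmax, ymax = raster.grid.extent

    def breaks(lo, hi):
        cuts = np.linspace(lo, hi, k + 1)
        jitter = (hi - lo) / k * 0.25
        cuts[1:-1] += rng.uniform(-jitter, jitter, size=k - 1)
        return cuts

    xs, ys = breaks(xmin, xmax), breaks(ymin, ymax)
    res_mask = raster.mask("residential")
    rows = []
    nid = 0
    for i in range(k):
        for j in range(k):
            poly = box(xs[j], ys[i], xs[j + 1], ys[i + 1])
            rr0, cc0, _ = raster.grid.cell_of(xs[j] + 1e-9, ys[i] + 1e-9)
            rr1, cc1, _ = raster.grid.cell_of(xs[j + 1] - 1e-9, ys[i + 1] - 1e-9)
            block = res_mask[int(rr0) : int(rr1) + 1, int(cc0) : int(cc1) + 1]
            res_frac = float(block.mean()) if block.size else 0.0
            if res_frac < 0.02:
                density = 0.0
            else:
                density = float(50 + 24000 * res_frac**1.5 * rng.lognormal(0.0, 0.3))
            if density == 0:
                over65, one_person, no_child = 0.0, 0.0, 0.0
            else:
                over65 = float(np.clip(rng.normal(18, 6), 0, 100))
                one_person = float(np.clip(rng.normal(35, 10), 0, 100))
                no_child = float(np.clip(rng.normal(55, 12), 0, 100))
            rows.append(
                {
                    "neighborhood_id": nid,
                    "population_density": density,
                    "pct_over_65": over65,
                    "pct_one_person": one_person,
                    "pct_no_child": no_child,
                    "geometry": poly,
                }
            )
            nid += 1
    return pd.DataFrame(rows)


def make_runners(
    seed: int,
    n_users: int,
    archetype_fractions: dict | None = None,
    specs: dict | None = None,
) -> list[UserProfile]:
    """Draw a runner population from the archetype mixture.

    Per-user annual run counts follow a Gamma distribution with the archetype
    mean and a 25% coefficient of variation (runner heterogeneity); baselines
    are Gaussian, floored at 500 m. Bursty users receive a contiguous active
    window of weeks within the year.
    """
    if n_users < 2:
        raise ValueError("need at least 2 users")
    fractions = dict(DEFAULT_FRACTIONS if archetype_fractions is None else archetype_fractions)
    specs = dict(DEFAULT_ARCHETYPES if specs is None else specs)
    if abs(sum(fractions.values()) - 1.0) > 1e-6:
        raise ValueError("archetype fractions must sum to 1")
    missing = set(fractions) - set(specs)
    if missing:
        raise ValueError(f"no spec for archetypes {sorted(missing)}")

    rng = np.random.default_rng(seed)
    labels = list(fractions)
    assignment = rng.choice(len(labels), size=n_users, p=[fractions[l] for l in labels])
    users = []
    for uid in range(n_users):
        spec = specs[labels[assignment[uid]]]
        annual = float(rng.gamma(16.0, spec.annual_run_count_mean / 16.0))
        baseline = float(max(500.0, rng.normal(spec.baseline_distance_mean, spec.baseline_distance_sd)))
        if spec.spread == "bursty":
            wlen = int(rng.integers(spec.active_weeks_min, spec.active_weeks_max + 1))
            wstart = int(rng.integers(0, 52))
        else:
            wlen = wstart = None
        users.append(
            UserProfile(
                user_id=uid,
                archetype=spec.label,
                annual_runs=annual,
                baseline_m=baseline,
                sensitivity=spec.situation_sensitivity,
                active_week_start=wstart,
                active_week_len=wlen,
                diurnal_prefs=spec.diurnal_prefs,
                weekday_prefs=spec.weekday_prefs,
            )
        )
    return users


def _start_cell_weights(raster: LanduseRaster) -> np.ndarray:
    """Sampling weights favoring residential cells and their surroundings."""
    res = raster.mask("residential")
    if res.any():
        d = ndimage.distance_transform_edt(~res)
        w = np.where(res, 8.0, np.where(d <= 2, 4.0, 1.0))
    else:
        w = np.ones(raster.classes.shape)
    return (w / w.sum()).ravel()


def _match_effects(
    effects: list[SituationEffect],
    run_items: dict,
) -> float:
    delta = 0.0
    for eff in effects:
        if all(run_items.get(f) == v for f, v in eff.items.items()):
            delta += eff.delta_m
    return delta


def simulate_runs(
    seed: int,
    users: list[UserProfile],
    world,
    effect_spec: list[SituationEffect] | None = None,
    horizon_years: int = 4,
    noise_sd: float = 300.0,
    start_date: str = "2013-03-23",
    aborted_run_prob: float = 0.02,
    missing_weather_prob: float = 0.01,
    geo_stack: GeoContextStack | None = None,
    bins: BinningScheme | None = None,
) -> pd.DataFrame:
    """Simulate run records for a user population.

    ``world`` is the ``(LanduseRaster, neighborhoods)`` pair from
    :func:`make_landscape` (the neighborhood table is unused here but accepted
    for convenience). Each run's distance is::

        baseline + sum(matched effect deltas) * sensitivity + N(0, noise_sd)

    clipped below at 50 m. A small fraction of runs are "aborted" (uniform
    50-150 m, exercising the <100 m cleaning rule) or carry a missing weather
    type. Effects on temporal/weather features are matched from the record
    itself; effects on geographic features additionally require ``geo_stack``
    and ``bins`` to resolve the start cell's categories.

    Returns a DataFrame with the canonical run-table columns.
    """
    raster = world[0] if isinstance(world, tuple) else world
    effects = list(effect_spec or [])
    geo_features_needed = sorted(
        {f for e in effects for f in e.features if FEATURE_CATEGORY[f] in ("topographical", "demographical")}
    )
    if geo_features_needed and (geo_stack is None or bins is None):
        raise ValueError(
            f"effects reference geographic features {geo_features_needed}; pass geo_stack and bins"
        )
    if horizon_years < 1:
        raise ValueError("horizon must be at least 1 year")

    rng = np.random.default_rng(seed)
    cell_p = _start_cell_weights(raster)
    grid = raster.grid
    t0 = _dt.date.fromisoformat(start_date)
    n_weeks = horizon_years * 52

    records = []
    activity_id = 0
    for user in users:
        n_runs = int(round(user.annual_runs * horizon_years))
        if n_runs == 0:
            continue
        # Weeks follow a stratified, yearly-repeating pattern: each year
        # spreads its runs evenly over the user's active weeks (bursty users'
        # sub-period, regular users' whole year). Because every 52-week
        # window then contains one full yearly pattern, the most-active-
        # window statistic identifies the planted annual rate instead of
        # inflating it by max-selection over random weekly fluctuations.
        if user.active_week_len is not None:
            slots = [(user.active_week_start + o) % 52 for o in range(user.active_week_len)]
        else:
            slots = list(range(52))
        per_year = [
            n_runs // horizon_years + (1 if y < n_runs % horizon_years else 0)
            for y in range(horizon_years)
        ]
        weeks = np.array(
            [
                y * 52 + slots[(i * len(slots)) // ny]
                for y, ny in enumerate(per_year)
                for i in range(ny)
            ],
            dtype=int,
        )
        n_runs = len(weeks)
        weekday = rng.choice(7, size=n_runs, p=np.asarray(user.weekday_prefs) / sum(user.weekday_prefs))
        slot = rng.choice(8, size=n_runs, p=np.asarray(user.diurnal_prefs) / sum(user.diurnal_prefs))
        minute_in_slot = rng.integers(0, 180, size=n_runs)
        second = rng.integers(0, 60, size=n_runs)

        flat = rng.choice(cell_p.size, size=n_runs, p=cell_p)
        rows_, cols_ = np.unravel_index(flat, raster.classes.shape)
        jx = rng.uniform(0, grid.cell_size, size=n_runs)
        jy = rng.uniform(0, grid.cell_size, size=n_runs)
        xs = grid.origin[0] + cols_ * grid.cell_size + jx
        ys = grid.origin[1] + rows_ * grid.cell_size + jy

        noise = rng.normal(0.0, noise_sd, size=n_runs)
        aborted = rng.random(n_runs) < aborted_run_prob
        aborted_dist = rng.uniform(50, 150, size=n_runs)
        missing_weather = rng.random(n_runs) < missing_weather_prob

        geo_cats = None
        if geo_features_needed:
            vals = geo_stack.geo_values_at(rows_, cols_)
            geo_cats = {
                f: bins.bin_geo_values(f, np.nan_to_num(vals[f].to_numpy(), nan=0.0))
                for f in geo_features_needed
            }

        for i in range(n_runs):
            ts = _dt.datetime.combine(
                t0 + _dt.timedelta(weeks=int(weeks[i])), _dt.time()
            ) + _dt.timedelta(
                days=int(weekday[i]) - (t0 + _dt.timedelta(weeks=int(weeks[i]))).weekday(),
                hours=int(slot[i]) * 3,
                minutes=int(minute_in_slot[i]),
                seconds=int(second[i]),
            )
            month = ts.month
            temp = float(rng.normal(MONTHLY_TEMP_MEAN[month - 1], 3.5))
            season = _SEASON_OF_MONTH[month - 1]
            weather = WEATHER_TYPES[rng.choice(9, p=_WEATHER_P[season])]
            wind = WIND_TYPES[rng.choice(5, p=_WIND_P)]
            humidity = HUMIDITY_TYPES[rng.choice(3, p=_HUMIDITY_P)]

            run_items = temporal_items(ts)
            run_items["temperature"] = temperature_bin(temp)
            run_items["weather"] = weather
            run_items["wind"] = wind
            run_items["humidity"] = humidity
            if geo_cats is not None:
                for f in geo_features_needed:
                    run_items[f] = geo_cats[f][i]

            delta = _match_effects(effects, run_items) * user.sensitivity
            if aborted[i]:
                dist = float(aborted_dist[i])
            else:
                dist = float(max(50.0, user.baseline_m + delta + noise[i]))

            records.append(
                (
                    activity_id,
                    user.user_id,
                    round(dist, 1),
                    ts,
                    round(float(xs[i]), 2),
                    round(float(ys[i]), 2),
                    "" if missing_weather[i] else weather,
                    round(temp, 1),
                    wind,
                    humidity,
                )
            )
            activity_id += 1

    return pd.DataFrame(records, columns=RUN_CSV_COLUMNS)


def write_runs_csv(path: str | Path, runs: pd.DataFrame) -> None:
    out = runs.copy()
    out["start_timestamp"] = pd.to_datetime(out["start_timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_runs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"weather_type": str, "wind_type": str, "humidity_type": str})
    df["start_timestamp"] = pd.to_datetime(df["start_timestamp"], errors="coerce")
    return df
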