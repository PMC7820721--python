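"""End-to-end pipeline: simulate -> enrich -> prepare -> cluster -> mine -> report.

One global seed fans out into per-stage child seeds (via ``SeedSequence``), so
re-running a single stage is reproducible, and the whole report is a pure
function of (config, seed). Every stage persists its artifacts under the
output directory:

* ``landuse.tif``, ``neighborhoods.geojson``, ``runs.csv``, ``users.csv``
* ``bins.json``, ``dist_<class>.tif``, ``cov_<class>.tif``
* ``transactions.csv``, ``weekly.csv``, ``drop_log.json``
* ``linkage.csv``, ``labels.csv``, ``cluster_profiles.csv``
* ``cluster<k>/`` mining tables and ``report.json``
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_runners, geoio, preprocess, situation_miner, synthetic_world
from .features import FEATURE_CATEGORY, LANDUSE_CLASSES
from .geo_context import BinningScheme, GeoContextStack
from .synthetic_world import RunnerArchetypeSpec, SituationEffect

logger = logging.getLogger(__name__)

#: The six headline features whose value histograms the report always includes.
HEADLINE_FEATURES = (
    "hour",
    "weekday",
    "temperature",
    "dist_residential",
    "dist_parks",
    "population_density",
)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    # world
    width_cells: int = 80
    height_cells: int = 80
    cell_size: float = 100.0
    class_mix: dict | None = None
    n_neighborhoods_side: int = 4
    # population
    n_users: int = 500
    archetype_fractions: dict = field(default_factory=lambda: dict(synthetic_world.DEFAULT_FRACTIONS))
    archetypes: dict = field(
        default_factory=lambda: {k: dataclasses.asdict(v) for k, v in synthetic_world.DEFAULT_ARCHETYPES.items()}
    )
    # simulation
    horizon_years: int = 4
    noise_sd: float = 300.0
    effects: list = field(
        default_factory=lambda: [
            {"items": {"weekday": "Sunday", "hour": "[09,12)"}, "delta_m": 800.0},
            {"items": {"temperature": "[6,14)"}, "delta_m": 400.0},
        ]
    )
    # cleaning
    min_distance_m: float = 100.0
    min_runs: int = 10
    # clustering
    cut_threshold: float | None = None
    n_clusters: int = 2
    # mining
    sigma: float = 30.0
    mode: str = "exhaustive"
    max_len: int = 3
    top_k: int = 10

    def __post_init__(self):
        # canonical YAML-stable form: prefs as lists
        for spec in self.archetypes.values():
            for key in ("diurnal_prefs", "weekday_prefs"):
                if key in spec:
                    spec[key] = [float(v) for v in spec[key]]

    def archetype_specs(self) -> dict:
        return {
            k: RunnerArchetypeSpec(**{**v, "diurnal_prefs": tuple(v["diurnal_prefs"]), "weekday_prefs": tuple(v["weekday_prefs"])})
            for k, v in self.archetypes.items()
        }

    def effect_spec(self) -> list[SituationEffect]:
        return [SituationEffect(items=dict(e["items"]), delta_m=float(e["delta_m"])) for e in self.effects]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    raster, hoods = synthetic_world.make_landscape(
        _child_seed(config.seed, 0),
        config.width_cells,
        config.height_cells,
        config.class_mix,
        cell_size=config.cell_size,
        n_neighborhoods_side=config.n_neighborhoods_side,
    )
    users = synthetic_world.make_runners(
        _child_seed(config.seed, 1), config.n_users, config.archetype_fractions, config.archetype_specs()
    )
    effects = config.effect_spec()
    needs_geo = any(
        FEATURE_CATEGORY[f] in ("topographical", "demographical") for e in effects for f in e.features
    )
    geo_stack = bins = None
    if needs_geo:
        geo_stack = GeoContextStack.build(raster, hoods)
        bins = geo_stack.fit_bins()
    runs = synthetic_world.simulate_runs(
        _child_seed(config.seed, 2),
        users,
        (raster, hoods),
        effects,
        horizon_years=config.horizon_years,
        noise_sd=config.noise_sd,
        geo_stack=geo_stack,
        bins=bins,
    )
    geoio.write_geotiff(out / "landuse.tif", raster.classes, raster.grid.origin, raster.grid.cell_size)
    geoio.write_neighborhoods_geojson(out / "neighborhoods.geojson", hoods)
    synthetic_world.write_runs_csv(out / "runs.csv", runs)
    pd.DataFrame([dataclasses.asdict(u) for u in users]).to_csv(out / "users.csv", index=False)
    logger.info("simulate: %d users, %d runs", len(users), len(runs))


def _load_world(out: Path):
    classes, origin, cell_size = geoio.read_geotiff(out / "landuse.tif")
    from .geo_context import Grid, LanduseRaster

    grid = Grid(origin=origin, cell_size=cell_size, width=classes.shape[1], height=classes.shape[0])
    raster = LanduseRaster(grid=grid, classes=classes)
    hoods = geoio.read_neighborhoods_geojson(out / "neighborhoods.geojson")
    return raster, hoods


def stage_enrich(config: PipelineConfig, out: Path) -> GeoContextStack:
    raster, hoods = _load_world(out)
    stack = GeoContextStack.build(raster, hoods)
    bins = stack.fit_bins()
    bins.to_json(out / "bins.json")
    for c in LANDUSE_CLASSES:
        if c in stack.distances:
            geoio.write_geotiff(out / f"dist_{c}.tif", stack.distances[c].values, raster.grid.origin, raster.grid.cell_size)
        geoio.write_geotiff(out / f"cov_{c}.tif", stack.coverages[c].values, raster.grid.origin, raster.grid.cell_size)
    return stack


def stage_prepare(config: PipelineConfig, out: Path, stack: GeoContextStack | None = None) -> None:
    if stack is None:
        raster, hoods = _load_world(out)
        stack = GeoContextStack.build(raster, hoods)
    bins = BinningScheme.from_json(out / "bins.json")
    runs = synthetic_world.read_runs_csv(out / "runs.csv")
    n_input = len(runs)
    cleaned, drops = preprocess.clean_runs(runs, stack)
    retained = preprocess.filter_sparse_users(cleaned, config.min_runs)
    drops["sparse_users"] = len(cleaned) - len(retained)
    drops["retained"] = len(retained)
    drops["input"] = n_input
    (out / "drop_log.json").write_text(json.dumps(drops, indent=1))
    tx = preprocess.build_transactions(retained, stack, bins)
    preprocess.write_transactions_csv(out / "transactions.csv", tx)
    preprocess.weekly_matrix(retained).to_csv(out / "weekly.csv")
    logger.info("prepare: retained %d/%d runs", len(retained), n_input)


def stage_cluster(config: PipelineConfig, out: Path) -> None:
    matrix = preprocess.WeeklyActivityMatrix.from_csv(out / "weekly.csv")
    D = cluster_runners.pairwise_dtw(matrix)
    Z = cluster_runners.ward_linkage(D)
    threshold = config.cut_threshold
    if threshold is None:
        threshold = cluster_runners.threshold_for_k(Z, config.n_clusters)
    labels = cluster_runners.cut_dendrogram(Z, threshold)
    pd.DataFrame(Z, columns=["a", "b", "height", "size"]).to_csv(out / "linkage.csv", index=False)
    pd.DataFrame({"user_id": matrix.user_ids, "cluster": labels}).to_csv(out / "labels.csv", index=False)
    prof = cluster_runners.cluster_profile(labels, matrix)
    prof.assign(mean_weekly_sequence=[";".join(f"{v:.3f}" for v in s) for s in prof["mean_weekly_sequence"]]).to_csv(
        out / "cluster_profiles.csv", index=False
    )
    logger.info("cluster: cut at %.3f -> %d clusters", threshold, len(prof))


def stage_mine(config: PipelineConfig, out: Path) -> None:
    tx = preprocess.read_transactions_csv(out / "transactions.csv")
    labels = pd.read_csv(out / "labels.csv")
    bins = BinningScheme.from_json(out / "bins.json")
    tx = tx.merge(labels, on="user_id")
    for c in sorted(labels["cluster"].unique()):
        sub = tx[tx["cluster"] == c]
        cdir = out / f"cluster{c}"
        cdir.mkdir(exist_ok=True)
        situation_miner.feature_variability(sub).to_csv(cdir / "variability.csv", index=False)
        for f in HEADLINE_FEATURES:
            situation_miner.value_histogram(sub, f, bins).to_csv(cdir / f"hist_{f}.csv", index=False)
        itemlists, weights = situation_miner.transactions_from_dataframe(sub)
        itemsets = situation_miner.mine(itemlists, weights, config.sigma, config.mode, config.max_len)
        situation_miner.itemsets_to_csv(cdir / "itemsets.csv", itemsets)
        for cat in ("temporal", "weather", "topographical", "demographical", "all"):
            pos, neg = situation_miner.top_situations(itemsets, cat, config.top_k)
            pos.to_csv(cdir / f"top_{cat}_positive.csv", index=False)
            neg.to_csv(cdir / f"top_{cat}_negative.csv", index=False)
        logger.info("mine: cluster %d -> %d itemsets", c, len(itemsets))


def stage_report(config: PipelineConfig, out: Path) -> dict:
    profiles = pd.read_csv(out / "cluster_profiles.csv")
    drops = json.loads((out / "drop_log.json").read_text())
    report = {
        "seed": config.seed,
        "n_users_clustered": int(profiles["n_users"].sum()),
        "n_clusters": int(len(profiles)),
        "clusters": profiles.drop(columns=["mean_weekly_sequence"]).to_dict(orient="records"),
        "drop_log": drops,
        "mining": {"sigma": config.sigma, "mode": config.mode, "max_len": config.max_len},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


_STAGES = ("simulate", "enrich", "prepare", "cluster", "mine", "report")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages in order; returns the report dict.

    Any stage failure aborts with the stage name attached to the exception.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    stack = None
    try:
        stage = "simulate"
        stage_simulate(config, out)
        stage = "enrich"
        stack = stage_enrich(config, out)
        stage = "prepare"
        stage_prepare(config, out, stack)
        stage = "cluster"
        stage_cluster(config, out)
        stage = "mine"
        stage_mine(config, out)
        stage = "report"
        return stage_report(config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
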