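import numpy as np
import pandas as pd
import pytest

from runsit.features import LANDUSE_CODE
from runsit.synthetic_world import (
    DEFAULT_ARCHETYPES,
    RunnerArchetypeSpec,
    SituationEffect,
    make_landscape,
    make_runners,
    simulate_runs,
    read_runs_csv,
    write_runs_csv,
    RUN_CSV_COLUMNS,
)


def test_landscape_contains_all_classes_under_uniform_mix():
    mix = {c: 1 / 9 for c in LANDUSE_CODE}
    raster, hoods = make_landscape(1, 50, 50, mix)
    assert raster.present_classes() == set(LANDUSE_CODE)
    assert len(hoods) == 16


def test_landscape_determinism():
    a, ha = make_landscape(3, 30, 30)
    b, hb = make_landscape(3, 30, 30)
    np.testing.assert_array_equal(a.classes, b.classes)
    pd.testing.assert_frame_equal(
        ha.drop(columns="geometry"), hb.drop(columns="geometry")
    )
    assert all(ga.equals(gb) for ga, gb in zip(ha["geometry"], hb["geometry"]))


def test_landscape_degenerate_single_class():
    raster, _ = make_landscape(2, 20, 20, {"residential": 1.0})
    assert (raster.classes == LANDUSE_CODE["residential"]).all()


def test_landscape_patches_are_contiguous_not_iid():
    raster, _ = make_landscape(5, 40, 40)
    # spatial autocorrelation: neighbors share a class far more often than chance
    same = (raster.classes[:, 1:] == raster.classes[:, :-1]).mean()
    assert same > 0.6


def test_landscape_rejects_bad_mix_and_size():
    with pytest.raises(ValueError, match="unknown"):
        make_landscape(1, 20, 20, {"moon_base": 1.0})
    with pytest.raises(ValueError):
        make_landscape(1, 5, 20)
    with pytest.raises(ValueError):
        make_landscape(1, 20, 20, {"parks": 0.5})  # does not sum to 1


def test_neighborhoods_tile_extent_without_overlap():
    raster, hoods = make_landscape(11, 30, 30)
    from shapely.ops import unary_union

    union = unary_union(list(hoods["geometry"]))
    xmin, ymin, xmax, ymax = raster.grid.extent
    assert union.area == pytest.approx((xmax - xmin) * (ymax - ymin))
    assert sum(g.area for g in hoods["geometry"]) == pytest.approx(union.area)


def test_runner_archetype_assignment_fractions():
    users = make_runners(1, 1000, {"sporadic": 0.8, "regular": 0.2})
    n_sporadic = sum(u.archetype == "sporadic" for u in users)
    assert 740 <= n_sporadic <= 860
    all_regular = make_runners(2, 50, {"regular": 1.0})
    assert all(u.archetype == "regular" for u in all_regular)


def test_runner_annual_count_within_15pct_of_spec():
    users = make_runners(9, 500, {"sporadic": 1.0})
    mean = np.mean([u.annual_runs for u in users])
    assert 29 <= mean <= 39


def test_sporadic_users_concentrated_regular_spread():
    users = make_runners(4, 200)
    for u in users:
        if u.archetype == "sporadic":
            assert u.active_week_len is not None and u.active_week_len <= 30
        else:
            assert u.active_week_len is None


def test_make_runners_rejects_tiny_population():
    with pytest.raises(ValueError):
        make_runners(1, 1)


@pytest.fixture(scope="module")
def small_world():
    return make_landscape(7, 30, 30)


def test_simulate_determinism_and_columns(small_world):
    users = make_runners(5, 20)
    a = simulate_runs(5, users, small_world, horizon_years=2)
    b = simulate_runs(5, users, small_world, horizon_years=2)
    pd.testing.assert_frame_equal(a, b)
    assert list(a.columns) == RUN_CSV_COLUMNS


def test_simulate_empty_users_and_horizon(small_world):
    assert len(simulate_runs(1, [], small_world)) == 0
    users = make_runners(6, 10)
    runs = simulate_runs(6, users, small_world, horizon_years=4)
    span = runs["start_timestamp"].max() - runs["start_timestamp"].min()
    assert span <= pd.Timedelta(days=4 * 366)


def test_simulate_no_noise_no_effects_hits_baseline(small_world):
    users = make_runners(8, 5)
    runs = simulate_runs(
        8, users, small_world, effect_spec=[], noise_sd=0.0, aborted_run_prob=0.0, horizon_years=1
    )
    baselines = {u.user_id: u.baseline_m for u in users}
    for uid, grp in runs.groupby("user_id"):
        assert np.allclose(grp["total_distance_m"], round(baselines[uid], 1))


def test_planted_sunday_effect_contrast(small_world):
    spec = RunnerArchetypeSpec(label="unit", annual_run_count_mean=60.0, situation_sensitivity=1.0)
    users = make_runners(3, 60, {"unit": 1.0}, {"unit": spec})
    effect = SituationEffect({"weekday": "Sunday"}, 800.0)
    runs = simulate_runs(
        3, users, small_world, [effect], horizon_years=2, noise_sd=100.0, aborted_run_prob=0.0
    )
    assert len(runs) >= 2000
    is_sunday = runs["start_timestamp"].dt.weekday == 6
    contrast = runs.loc[is_sunday, "total_distance_m"].mean() - runs.loc[~is_sunday, "total_distance_m"].mean()
    assert contrast == pytest.approx(800.0, abs=60.0)


def test_effect_scaled_by_archetype_sensitivity(small_world):
    spec = RunnerArchetypeSpec(label="x2", annual_run_count_mean=60.0, situation_sensitivity=2.0)
    users = make_runners(3, 60, {"x2": 1.0}, {"x2": spec})
    effect = SituationEffect({"weekday": "Sunday"}, 800.0)
    runs = simulate_runs(3, users, small_world, [effect], horizon_years=2, noise_sd=100.0, aborted_run_prob=0.0)
    is_sunday = runs["start_timestamp"].dt.weekday == 6
    contrast = runs.loc[is_sunday, "total_distance_m"].mean() - runs.loc[~is_sunday, "total_distance_m"].mean()
    assert contrast == pytest.approx(1600.0, abs=120.0)


def test_start_locations_favor_residential(small_world):
    raster, _ = small_world
    users = make_runners(2, 40)
    runs = simulate_runs(2, users, small_world, horizon_years=1)
    rows, cols, inside = raster.grid.cell_of(runs["start_x"].to_numpy(), runs["start_y"].to_numpy())
    assert inside.all()
    res_frac_runs = (raster.classes[rows, cols] == LANDUSE_CODE["residential"]).mean()
    res_frac_cells = (raster.classes == LANDUSE_CODE["residential"]).mean()
    assert res_frac_runs > 1.5 * res_frac_cells


def test_effect_on_geo_feature_requires_context(small_world):
    users = make_runners(1, 5)
    with pytest.raises(ValueError, match="geo_stack"):
        simulate_runs(1, users, small_world, [SituationEffect({"dist_parks": "0"}, 500.0)])


def test_effect_spec_validation():
    with pytest.raises(ValueError):
        SituationEffect({"not_a_feature": "x"}, 100.0)
    with pytest.raises(ValueError):
        SituationEffect({"weekday": "Sunday"}, float("nan"))


def test_runs_csv_roundtrip(tmp_path, small_world):
    users = make_runners(1, 8)
    runs = simulate_runs(1, users, small_world, horizon_years=1)
    path = tmp_path / "runs.csv"
    write_runs_csv(path, runs)
    back = read_runs_csv(path)
    assert list(back.columns) == RUN_CSV_COLUMNS
    pd.testing.assert_series_equal(back["total_distance_m"], runs["total_distance_m"])
    assert (pd.to_datetime(back["start_timestamp"]) == runs["start_timestamp"]).all()


def test_default_archetypes_match_study_conditions():
    assert DEFAULT_ARCHETYPES["sporadic"].annual_run_count_mean == 34.0
    assert DEFAULT_ARCHETYPES["regular"].annual_run_count_mean == 94.0
    assert (
        DEFAULT_ARCHETYPES["sporadic"].situation_sensitivity
        > DEFAULT_ARCHETYPES["regular"].situation_sensitivity
    )
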