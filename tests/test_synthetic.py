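"""Scenario generator: construction invariants, determinism, export round trip."""

import numpy as np
import pytest

from ambientpop.grid_io import GridSpec, read_raster, read_stats, read_zones
from ambientpop.synthetic import (ScenarioConfig, ScenarioError,
                                  export_scenario, generate_coefficient_table,
                                  generate_scenario)

TINY_GRID = GridSpec(110.0, 35.0, 0.01, 1, 1)
SMALL_GRID = GridSpec(110.0, 35.0, 0.01, 12, 12)


def _small_cfg(**kw):
    base = dict(grid=SMALL_GRID, n_counties=9, n_towns_per_county=2,
                n_hotspots=3, n_days=4, holiday_dates=("2018-03-02",), seed=0)
    base.update(kw)
    return ScenarioConfig(**base)


def test_degenerate_single_cell_scenario():
    """1 county, 1 cell, no noise: stats equal the cell and every non-holiday
    day equals exp((ln P - b)/a)."""
    cfg = ScenarioConfig(grid=TINY_GRID, n_counties=1, n_towns_per_county=1,
                         n_hotspots=1, noise_sigma=0.0, day_sigma=0.0,
                         n_days=3, holiday_dates=("2018-03-02",), seed=5)
    scen = generate_scenario(cfg)
    p = scen.truth_pop.values[0, 0]
    assert scen.county_stats.total == pytest.approx(p)
    a = scen.a_true.values[0, 0]
    b = scen.b_true.values[0, 0]
    expected = np.exp((np.log(p) - b) / a)
    for date, raster in scen.daily_stack:
        if date in cfg.holidays:
            assert raster.values[0, 0] == pytest.approx(
                expected * cfg.holiday_inflation)
        else:
            assert raster.values[0, 0] == pytest.approx(expected)


def test_county_stats_equal_raster_sums_exactly():
    scen = generate_scenario(_small_cfg())
    labels = scen.zone_raster.labels.ravel()
    for i, zid in enumerate(scen.zone_raster.zone_ids):
        s = scen.truth_pop.values.ravel()[labels == i].sum()
        assert scen.county_stats.population_of(zid) == pytest.approx(s, rel=1e-6)


def test_town_stats_nest_in_counties():
    scen = generate_scenario(_small_cfg())
    town_labels = scen.town_raster.labels
    county_labels = scen.zone_raster.labels
    # every town's cells lie in exactly one county
    for t in range(scen.town_raster.n_zones):
        owners = np.unique(county_labels[town_labels == t])
        assert len(owners) == 1
    assert scen.town_stats.total == pytest.approx(scen.county_stats.total)


def test_same_seed_identical_different_seed_differs():
    s1 = generate_scenario(_small_cfg(seed=7))
    s2 = generate_scenario(_small_cfg(seed=7))
    s3 = generate_scenario(_small_cfg(seed=8))
    assert np.array_equal(s1.truth_pop.values, s2.truth_pop.values)
    assert np.array_equal(s1.daily_stack[0][1].values, s2.daily_stack[0][1].values)
    assert not np.array_equal(s1.truth_pop.values, s3.truth_pop.values)


def test_hotspot_peak_monotonicity():
    """Raising hotspot_peak never decreases any county population."""
    lo = generate_scenario(_small_cfg(hotspot_peak=200.0))
    hi = generate_scenario(_small_cfg(hotspot_peak=400.0))
    for zid in lo.county_stats.data["zone_id"]:
        assert hi.county_stats.population_of(zid) >= lo.county_stats.population_of(zid)


def test_counties_are_contiguous_partition():
    scen = generate_scenario(_small_cfg())
    labels = scen.zone_raster.labels
    assert (labels >= 0).all()
    # 4-connectivity flood check per county
    from scipy.ndimage import label as cc_label

    for i in range(scen.zone_raster.n_zones):
        _, n_comp = cc_label(labels == i)
        assert n_comp == 1


def test_config_validation():
    with pytest.raises(ScenarioError, match="exceed"):
        ScenarioConfig(grid=TINY_GRID, n_counties=2)
    with pytest.raises(ScenarioError, match="exclude 0"):
        _small_cfg(a_field=(0.0, 1.0))
    with pytest.raises(ScenarioError, match="hotspot_peak"):
        _small_cfg(background=600.0)


def test_daily_counts_nonnegative():
    scen = generate_scenario(_small_cfg(poisson_counts=True))
    for _, raster in scen.daily_stack:
        assert (raster.values >= 0).all()


def test_export_round_trip(tmp_path):
    scen = generate_scenario(_small_cfg(n_days=3))
    paths = export_scenario(scen, tmp_path)
    tifs = sorted(tmp_path.glob("counts_*.tif"))
    assert len(tifs) == 3
    stats_back = read_stats(paths["county_stats"])
    assert stats_back.data.equals(scen.county_stats.data)
    zones = read_zones(paths["counties"])
    assert set(zones.zone_ids) == set(scen.zone_raster.zone_ids)
    raster = read_raster(tifs[0])
    np.testing.assert_allclose(raster.values, scen.daily_stack[0][1].values)


def test_exported_scenario_runs_through_public_interfaces(tmp_path):
    """End-to-end through the file formats: rasterize zones, rebuild the table,
    allocate — no manual steps."""
    import datetime as dt

    from ambientpop.allocation import allocate_population, predict_weight_surface
    from ambientpop.gwr import GWRConfig, fit_gwr_loglinear
    from ambientpop.temporal import average_daily_counts, build_calendar_filter
    from ambientpop.zonal import county_totals, rasterize_zones

    scen = generate_scenario(_small_cfg())
    paths = export_scenario(scen, tmp_path)
    stack = []
    for p in sorted(tmp_path.glob("counts_*.tif")):
        date = dt.date.fromisoformat(p.stem.split("_")[1])
        stack.append((date, read_raster(p, units="counts")))
    cal = build_calendar_filter(2018, {3}, scen.config.holiday_dates)
    mean = average_daily_counts(stack, cal)
    zones = read_zones(paths["counties"])
    stats = read_stats(paths["county_stats"])
    zr = rasterize_zones(zones, mean.spec)
    table = county_totals(mean, zr, stats, zones)
    fit = fit_gwr_loglinear(table, GWRConfig(kernel="gaussian",
                                             bandwidth_mode="fixed",
                                             bandwidth=1e9))
    weights = predict_weight_surface(mean, zr, fit)
    surface, diag = allocate_population(weights, zr, stats)
    assert diag.max_relative_error() < 1e-6
    assert np.nansum(surface.values) == pytest.approx(stats.total, rel=1e-6)


def test_coefficient_table_truth_within_ranges():
    table, a_true, b_true = generate_coefficient_table(n_counties=50, seed=1)
    assert len(table) == 50
    assert (a_true >= 0.8).all() and (a_true <= 1.2).all()
    assert (b_true >= 0.0).all() and (b_true <= 1.0).all()
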