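"""Synthetic scenarios for exercising the full pipeline without any download.

A scenario bundles everything the pipeline consumes plus the ground truth it
tries to recover:

* a clustered "true" population surface (background level plus Gaussian-bump
  hotspots, with optional per-cell log-normal dispersion);
* smooth spatially varying log-linear coefficient fields a(u), b(u) linking
  population to the expected location count — the generative model inverts
  the regression law at cell level, so the expected count of cell j is
  ``exp((ln P_j - b_j) / a_j)`` with P the smooth presence surface; the
  cell-level dispersion (``noise_sigma``) enters the recorded truth only,
  emulating the imperfection of LBS counts as a population proxy;
* a contiguous county partition of the grid (nearest-seed growth on the cell
  lattice) with nested towns, and exact per-zone population sums playing the
  role of the statistical tables;
* a stack of daily count rasters with per-cell-day log-normal noise, where
  designated holiday dates are inflated by a constant factor to emulate
  travel-period contamination.

Counts are real-valued by default (the pipeline operates on averages); a
Poisson-rounding flag adds integer sampling noise.  Identical configs produce
bit-identical scenarios.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import box, union_all

from . import grid_io
from .grid_io import GridRaster, GridSpec, StatTable, Zone, ZoneSet
from .zonal import ZoneRaster

logger = logging.getLogger("ambientpop")


class ScenarioError(ValueError):
    pass


def _default_holidays() -> tuple[str, ...]:
    # four contaminated dates inside the default 30-day window
    return ("2018-03-05", "2018-03-12", "2018-03-19", "2018-03-26")


@dataclass(frozen=True)
class ScenarioConfig:
    """Desk-scale defaults: 100x100 grid of 0.01-degree cells, 400 counties
    with 4 towns each, 30 days with 4 contaminated holiday dates."""

    grid: GridSpec = GridSpec(
        origin_lon=110.0, origin_lat=35.0, cell_size=0.01, n_rows=100, n_cols=100
    )
    n_counties: int = 400
    n_towns_per_county: int = 4
    n_hotspots: int = 12
    hotspot_peak: float = 500.0       # persons/cell at a hotspot center
    hotspot_sigma_cells: tuple[float, float] = (3.0, 10.0)
    background: float = 5.0           # persons/cell away from hotspots
    a_field: tuple[float, float] = (0.8, 1.2)
    b_field: tuple[float, float] = (0.0, 1.0)
    field_mode: str = "ramp"          # "ramp" (bilinear) or "random" (smoothed)
    noise_sigma: float = 0.1          # cell-level log-normal sd on the truth
    day_sigma: float = 0.05           # per-cell-day log-normal sd on counts
    n_days: int = 30
    start_date: str = "2018-03-01"
    holiday_dates: tuple[str, ...] = field(default_factory=_default_holidays)
    holiday_inflation: float = 3.0
    poisson_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_field[0] <= 0:
            raise ScenarioError("a range must exclude 0 (log-linear law is increasing)")
        if self.noise_sigma < 0 or self.day_sigma < 0:
            raise ScenarioError("noise standard deviations must be >= 0")
        if not self.hotspot_peak > self.background >= 0:
            raise ScenarioError("require hotspot_peak > background >= 0")
        n_cells = self.grid.n_rows * self.grid.n_cols
        if self.n_counties > n_cells:
            raise ScenarioError(
                f"{self.n_counties} counties exceed {n_cells} cells"
            )

    @property
    def dates(self) -> list[dt.date]:
        d0 = dt.date.fromisoformat(self.start_date)
        return [d0 + dt.timedelta(days=i) for i in range(self.n_days)]

    @property
    def holidays(self) -> set[dt.date]:
        return {dt.date.fromisoformat(d) for d in self.holiday_dates}


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    truth_pop: GridRaster
    a_true: GridRaster
    b_true: GridRaster
    zone_raster: ZoneRaster          # county labels
    town_raster: ZoneRaster
    county_stats: StatTable          # exact per-county sums of truth_pop
    town_stats: StatTable
    daily_stack: list[tuple[dt.date, GridRaster]]

    def county_true_coefficients(self) -> pd.DataFrame:
        """Mean of the true coefficient fields over each county's cells."""
        labels = self.zone_raster.labels.ravel()
        inside = labels >= 0
        nz = self.zone_raster.n_zones
        n = np.bincount(labels[inside], minlength=nz).astype(float)
        a = np.bincount(labels[inside], weights=self.a_true.values.ravel()[inside],
                        minlength=nz)
        b = np.bincount(labels[inside], weights=self.b_true.values.ravel()[inside],
                        minlength=nz)
        with np.errstate(invalid="ignore"):
            return pd.DataFrame(
                {"zone_id": self.zone_raster.zone_ids, "a_true": a / n, "b_true": b / n}
            )


def _coefficient_field(
    lo: float, hi: float, shape: tuple[int, int], mode: str,
    rng: np.random.Generator, diagonal: int,
) -> np.ndarray:
    nr, nc = shape
    r = np.arange(nr)[:, None] / max(nr - 1, 1)
    c = np.arange(nc)[None, :] / max(nc - 1, 1)
    if mode == "ramp":
        # bilinear ramp; the two fields run along opposite diagonals
        frac = (c + r) / 2.0 if diagonal > 0 else (c + 1.0 - r) / 2.0
        return lo + (hi - lo) * frac
    if mode == "random":
        from scipy.ndimage import gaussian_filter

        f = gaussian_filter(rng.standard_normal(shape), sigma=min(nr, nc) / 5.0,
                            mode="nearest")
        if f.max() > f.min():
            f = (f - f.min()) / (f.max() - f.min())
        else:
            f = np.full(shape, 0.5)
        return lo + (hi - lo) * f
    raise ScenarioError(f"unknown field_mode '{mode}'")


def _nearest_seed_labels(
    shape: tuple[int, int], seeds: np.ndarray
) -> np.ndarray:
    """Assign each lattice cell to its nearest seed (Euclidean in index space,
    ties to the lowest seed index) — contiguous Voronoi-like regions."""
    nr, nc = shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cells = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d2 = ((cells[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).reshape(shape)


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Draw a complete scenario from the config (bit-reproducible per seed)."""
    rng = np.random.default_rng(config.seed)
    spec = config.grid
    nr, nc = spec.n_rows, spec.n_cols
    shape = (nr, nc)

    # --- true population: background + Gaussian hotspots, log-normal dispersion
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    pop_smooth = np.full(shape, config.background, dtype=float)
    centers = rng.uniform([0, 0], [nr, nc], size=(config.n_hotspots, 2))
    sigmas = rng.uniform(*config.hotspot_sigma_cells, size=config.n_hotspots)
    peaks = config.hotspot_peak * rng.uniform(0.5, 1.0, size=config.n_hotspots)
    for (r0, c0), s, p in zip(centers, sigmas, peaks):
        pop_smooth += p * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * s**2))
    # noise_sigma is population/signal mismatch: the LBS signal tracks the
    # smooth presence surface, the recorded truth carries cell-level dispersion
    pop = pop_smooth.copy()
    if config.noise_sigma > 0:
        pop *= np.exp(rng.normal(0.0, config.noise_sigma, size=shape))

    # --- smooth coefficient fields
    a = _coefficient_field(*config.a_field, shape, config.field_mode, rng, +1)
    b = _coefficient_field(*config.b_field, shape, config.field_mode, rng, -1)

    # --- county and nested town partitions by nearest-seed growth
    n_cells = nr * nc
    county_seed_flat = rng.choice(n_cells, size=config.n_counties, replace=False)
    county_seeds = np.column_stack(np.unravel_index(county_seed_flat, shape)).astype(float)
    county_labels = _nearest_seed_labels(shape, county_seeds)
    county_ids = [f"C{i:04d}" for i in range(config.n_counties)]

    town_labels = np.full(shape, -1, dtype=np.int64)
    town_ids: list[str] = []
    for i in range(config.n_counties):
        cells = np.flatnonzero(county_labels.ravel() == i)
        k = min(config.n_towns_per_county, cells.size)
        seeds_flat = rng.choice(cells, size=k, replace=False)
        seeds_rc = np.column_stack(np.unravel_index(seeds_flat, shape)).astype(float)
        cells_rc = np.column_stack(np.unravel_index(cells, shape)).astype(float)
        d2 = ((cells_rc[:, None, :] - seeds_rc[None, :, :]) ** 2).sum(axis=2)
        local = np.argmin(d2, axis=1)
        town_labels.ravel()[cells] = len(town_ids) + local
        town_ids.extend(f"{county_ids[i]}T{t:02d}" for t in range(k))

    zone_raster = ZoneRaster(spec, county_labels, county_ids)
    town_raster = ZoneRaster(spec, town_labels, town_ids)

    # --- exact zone statistics (the "sample survey" inputs)
    county_pop = np.bincount(county_labels.ravel(), weights=pop.ravel(),
                             minlength=config.n_counties)
    county_stats = StatTable(pd.DataFrame({"zone_id": county_ids, "population": county_pop}))
    town_pop = np.bincount(town_labels.ravel(), weights=pop.ravel(),
                           minlength=len(town_ids))
    town_stats = StatTable(pd.DataFrame({"zone_id": town_ids, "population": town_pop}))

    # --- daily count stack: invert the cell-level log-linear law on the
    # smooth surface (with noise_sigma = 0 the relation is exact in the truth)
    t_mean = np.exp((np.log(pop_smooth) - b) / a)
    holidays = config.holidays
    stack: list[tuple[dt.date, GridRaster]] = []
    for date in config.dates:
        day = t_mean.copy()
        if config.day_sigma > 0:
            day = day * np.exp(rng.normal(0.0, config.day_sigma, size=shape))
        if date in holidays:
            day = day * config.holiday_inflation
        if config.poisson_counts:
            day = rng.poisson(day).astype(float)
        stack.append((date, GridRaster(spec, day, units="counts")))

    return SyntheticScenario(
        config=config,
        truth_pop=GridRaster(spec, pop, units="persons"),
        a_true=GridRaster(spec, a, units=""),
        b_true=GridRaster(spec, b, units=""),
        zone_raster=zone_raster,
        town_raster=town_raster,
        county_stats=county_stats,
        town_stats=town_stats,
        daily_stack=stack,
    )


def generate_coefficient_table(
    n_counties: int = 200,
    extent: tuple[float, float, float, float] = (110.0, 30.0, 115.0, 35.0),
    a_field: tuple[float, float] = (0.8, 1.2),
    b_field: tuple[float, float] = (0.0, 1.0),
    x_range: tuple[float, float] = (1.0, 8.0),
    noise_sigma: float = 0.1,
    seed: int = 0,
):
    """County table drawn directly from the log-linear law (no aggregation).

    Anchors are scattered uniformly over the lon/lat extent; the true
    coefficient fields are bilinear ramps over the extent (a along one
    diagonal, b along the other); log-counts x are uniform draws, and
    ln(population) = a(u) x + b(u) + N(0, noise_sigma^2).  This is the clean
    benchmark for coefficient recovery: unlike the full scenario there is no
    zonal aggregation step, so the only error sources are the relation noise
    and the kernel's coefficient smoothing.

    Returns ``(CountyTable, a_true, b_true)`` with the truth evaluated at the
    anchors.
    """
    from .zonal import CountyTable

    rng = np.random.default_rng(seed)
    lon0, lat0, lon1, lat1 = extent
    lon = rng.uniform(lon0, lon1, n_counties)
    lat = rng.uniform(lat0, lat1, n_counties)
    u = (lon - lon0) / (lon1 - lon0)
    v = (lat - lat0) / (lat1 - lat0)
    a_true = a_field[0] + (a_field[1] - a_field[0]) * (u + v) / 2.0
    b_true = b_field[0] + (b_field[1] - b_field[0]) * (u + 1.0 - v) / 2.0
    x = rng.uniform(*x_range, n_counties)
    y = a_true * x + b_true + rng.normal(0.0, noise_sigma, n_counties)
    table = CountyTable(
        pd.DataFrame(
            {
                "zone_id": [f"S{i:04d}" for i in range(n_counties)],
                "population": np.exp(y),
                "lbs_total": np.exp(x),
                "n_cells": 1,
                "n_nodata_cells": 0,
                "anchor_lon": lon,
                "anchor_lat": lat,
            }
        )
    )
    return table, a_true, b_true


def zone_raster_to_polygons(zone_raster: ZoneRaster, parent: dict[str, str] | None = None) -> ZoneSet:
    """Dissolve a label raster into polygon zones (union of member cell boxes)."""
    spec = zone_raster.spec
    labels = zone_raster.labels
    zones = []
    for idx, zid in enumerate(zone_raster.zone_ids):
        rows, cols = np.nonzero(labels == idx)
        if rows.size == 0:
            continue
        boxes = [box(*_bounds(spec, r, c)) for r, c in zip(rows, cols)]
        geom = union_all(boxes)
        zones.append(Zone(zid, geom, grid_io._anchor_point(geom),
                          parent.get(zid) if parent else None))
    return ZoneSet(zones)


def _bounds(spec: GridSpec, r: int, c: int) -> tuple[float, float, float, float]:
    west, south, east, north = spec.cell_box(r, c)
    return (west, south, east, north)


def export_scenario(scenario: SyntheticScenario, directory: str | Path) -> dict[str, Path]:
    """Write the scenario in exactly the formats the pipeline ingests.

    Daily rasters as dated GeoTIFFs, county/town polygons as GeoJSON, label
    rasters as GeoTIFFs, statistics as CSV, plus the ground-truth surfaces.
    Returns the paths keyed by artifact name.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for date, raster in scenario.daily_stack:
        p = directory / f"counts_{date.isoformat()}.tif"
        grid_io.write_raster(raster, p)
        paths[f"counts_{date.isoformat()}"] = p

    county_zones = zone_raster_to_polygons(scenario.zone_raster)
    town_parent = {
        tid: tid.split("T")[0] for tid in scenario.town_raster.zone_ids
    }
    town_zones = zone_raster_to_polygons(scenario.town_raster, parent=town_parent)
    paths["counties"] = directory / "counties.geojson"
    grid_io.write_zones(county_zones, paths["counties"])
    paths["towns"] = directory / "towns.geojson"
    grid_io.write_zones(town_zones, paths["towns"])

    for name, raster in [
        ("truth_pop", scenario.truth_pop),
        ("a_true", scenario.a_true),
        ("b_true", scenario.b_true),
    ]:
        paths[name] = directory / f"{name}.tif"
        grid_io.write_raster(raster, paths[name])
    lbl = scenario.zone_raster
    paths["county_labels"] = directory / "county_labels.tif"
    grid_io.write_raster(GridRaster(lbl.spec, lbl.labels.astype(float)), paths["county_labels"])

    paths["county_stats"] = directory / "county_stats.csv"
    grid_io.write_stats(scenario.county_stats, paths["county_stats"])
    paths["town_stats"] = directory / "town_stats.csv"
    grid_io.write_stats(scenario.town_stats, paths["town_stats"])
    logger.info("exported scenario to %s (%d files)", directory, len(paths))
    return paths
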