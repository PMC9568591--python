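"""Zone rasterization and county-level aggregation of the mean count raster.

Cells are assigned to the zone whose polygon covers the cell CENTER; a center
on a shared boundary is resolved to the lowest zone index, so each cell
belongs to exactly one county and zonal sums partition the raster total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree, points

from .grid_io import GridRaster, GridSpec, StatTable, ZoneSet, _anchor_point

logger = logging.getLogger("ambientpop")


class ZonalError(ValueError):
    pass


@dataclass
class ZoneRaster:
    """Cell -> zone-index labels on a grid; -1 marks cells outside all zones."""

    spec: GridSpec
    labels: np.ndarray  # int array, shape = spec.shape
    zone_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != self.spec.shape:
            raise ZonalError(
                f"labels shape {self.labels.shape} != grid {self.spec.shape}"
            )
        if self.labels.max(initial=-1) >= len(self.zone_ids) or self.labels.min(initial=0) < -1:
            raise ZonalError("labels reference zone indices outside the id map")

    @property
    def n_zones(self) -> int:
        return len(self.zone_ids)

    def cells_of(self, index: int) -> np.ndarray:
        return np.flatnonzero(self.labels.ravel() == index)


@dataclass
class CountyTable:
    """Per-county regression inputs: population, aggregated count, anchors.

    Columns of ``data``: zone_id, population, lbs_total, n_cells,
    n_nodata_cells, anchor_lon, anchor_lat.  ``excluded`` lists counties
    dropped by the retention rule with their reason.
    """

    data: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["zone_id", "reason"])
    )

    def __post_init__(self) -> None:
        df = self.data
        if df["zone_id"].duplicated().any():
            raise ZonalError("duplicate zone_id in county table")
        if (df["n_cells"] < 1).any():
            raise ZonalError("retained county with zero cells")
        if (df["lbs_total"] < 0).any():
            raise ZonalError("negative aggregated count")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


def rasterize_zones(zones: ZoneSet, spec: GridSpec) -> ZoneRaster:
    """Label each grid cell with the index of the zone covering its center."""
    if len(zones) == 0:
        raise ZonalError("empty ZoneSet")
    lon, lat = spec.cell_centers()
    pts = points(np.column_stack([lon.ravel(), lat.ravel()]))
    tree = STRtree(pts)
    labels = np.full(lon.size, -1, dtype=np.int64)
    # iterate in index order: first (lowest-index) zone wins boundary ties
    for idx, zone in enumerate(zones.zones):
        hit = tree.query(zone.geometry, predicate="covers")
        free = hit[labels[hit] == -1]
        labels[free] = idx
    if (labels == -1).all():
        raise ZonalError("no grid cell center falls inside any zone")
    return ZoneRaster(spec, labels.reshape(spec.shape), list(zones.zone_ids))


def county_totals(
    mean_raster: GridRaster,
    zone_raster: ZoneRaster,
    stats: StatTable,
    zones: ZoneSet | None = None,
) -> CountyTable:
    """Aggregate the mean count raster to counties and join statistics.

    Per county: ``lbs_total`` is the sum of the mean raster over member cells
    (nodata cells contribute 0 and are tallied in ``n_nodata_cells``);
    the anchor is the polygon centroid when ``zones`` is given, otherwise the
    mean of member cell centers.  Counties with no cells, zero total count or
    zero population are excluded from the regression table and logged; they
    reappear at allocation time through the uniform fallback.
    """
    if not mean_raster.spec.approx_equal(zone_raster.spec):
        raise ZonalError("mean raster and zone raster grids do not match")
    labels = zone_raster.labels.ravel()
    values = mean_raster.values.ravel()
    nz = zone_raster.n_zones
    inside = labels >= 0
    filled = np.where(np.isnan(values), 0.0, values)
    lbs = np.bincount(labels[inside], weights=filled[inside], minlength=nz)
    n_cells = np.bincount(labels[inside], minlength=nz)
    n_nodata = np.bincount(
        labels[inside], weights=np.isnan(values)[inside].astype(float), minlength=nz
    ).astype(int)

    lon, lat = mean_raster.spec.cell_centers()
    lon, lat = lon.ravel(), lat.ravel()
    with np.errstate(invalid="ignore"):
        anchor_lon = np.bincount(labels[inside], weights=lon[inside], minlength=nz)
        anchor_lat = np.bincount(labels[inside], weights=lat[inside], minlength=nz)
        anchor_lon = np.divide(anchor_lon, n_cells, out=np.full(nz, np.nan), where=n_cells > 0)
        anchor_lat = np.divide(anchor_lat, n_cells, out=np.full(nz, np.nan), where=n_cells > 0)
    if zones is not None:
        by_id = {z.zone_id: z for z in zones.zones}
        for i, zid in enumerate(zone_raster.zone_ids):
            if zid in by_id:
                anchor_lon[i], anchor_lat[i] = _anchor_point(by_id[zid].geometry)

    pop_map = dict(zip(stats.data["zone_id"], stats.data["population"]))
    rows, dropped = [], []
    for i, zid in enumerate(zone_raster.zone_ids):
        pop = pop_map.get(zid)
        if pop is None:
            dropped.append((zid, "no statistics"))
            continue
        if n_cells[i] == 0:
            dropped.append((zid, "no cells"))
            continue
        if lbs[i] <= 0:
            dropped.append((zid, "no signal"))
            continue
        if pop <= 0:
            dropped.append((zid, "zero population"))
            continue
        rows.append((zid, pop, lbs[i], int(n_cells[i]), n_nodata[i], anchor_lon[i], anchor_lat[i]))
    for zid in stats.data["zone_id"]:
        if zid not in set(zone_raster.zone_ids):
            dropped.append((zid, "not in zone raster"))
    if dropped:
        logger.warning("excluded %d counties from the regression table", len(dropped))
    data = pd.DataFrame(
        rows,
        columns=["zone_id", "population", "lbs_total", "n_cells",
                 "n_nodata_cells", "anchor_lon", "anchor_lat"],
    )
    excluded = pd.DataFrame(dropped, columns=["zone_id", "reason"])
    return CountyTable(data, excluded)
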