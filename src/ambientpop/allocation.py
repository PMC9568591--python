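"""Mass-conserving dasymetric allocation of county populations to grid cells.

Each cell's weight is the local model's prediction exp(b_i) * T_j^{a_i} from
its county's coefficients and the cell's mean count T_j; the county statistic
is then redistributed proportionally, pop_ij = County_i * w_ij / sum_j w_ij,
so county totals are conserved exactly (the pycnophylactic property).
Counties without coefficients (dropped from the regression) and counties whose
weights sum to zero fall back to uniform allocation over their cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import GridRaster, StatTable
from .gwr import GWRFit
from .zonal import ZoneRaster, ZonalError

logger = logging.getLogger("ambientpop")


class AllocationError(ValueError):
    pass


@dataclass
class AllocationDiagnostics:
    """Per-county conservation audit: target vs achieved sums, fallbacks."""

    table: pd.DataFrame  # zone_id, target, achieved, n_cells, fallback

    def max_relative_error(self) -> float:
        t = self.table
        pos = t["target"] > 0
        if not pos.any():
            return 0.0
        return float(
            (np.abs(t.loc[pos, "achieved"] - t.loc[pos, "target"]) / t.loc[pos, "target"]).max()
        )


def predict_weight_surface(
    mean_raster: GridRaster, zone_raster: ZoneRaster, fit: GWRFit
) -> GridRaster:
    """Grid weight surface from per-county log-linear coefficients.

    Cell j in county i with mean count T_j gets weight exp(b_i) * T_j^{a_i}
    (zero when T_j = 0, the a > 0 limit); nodata count cells get weight 0 and
    are tallied; counties absent from the fit get uniform weight 1.
    """
    if not mean_raster.spec.approx_equal(zone_raster.spec):
        raise AllocationError("mean raster and zone raster grids do not match")
    nz = zone_raster.n_zones
    idx_of = {zid: i for i, zid in enumerate(fit.zone_ids)}
    a_map = np.full(nz, np.nan)
    b_map = np.full(nz, np.nan)
    for i, zid in enumerate(zone_raster.zone_ids):
        j = idx_of.get(zid)
        if j is not None:
            a_map[i], b_map[i] = fit.a[j], fit.b[j]
    n_nonpos = int((a_map[~np.isnan(a_map)] <= 0).sum())
    if n_nonpos:
        logger.warning(
            "%d counties have a_i <= 0 (superlinear assumption violated); "
            "weights computed as specified", n_nonpos,
        )
    labels = zone_raster.labels
    inside = labels >= 0
    weights = np.full(zone_raster.spec.shape, np.nan)
    a_cell = np.where(inside, a_map[np.clip(labels, 0, None)], np.nan)
    b_cell = np.where(inside, b_map[np.clip(labels, 0, None)], np.nan)
    t = mean_raster.values
    n_nodata_counts = int((inside & np.isnan(t)).sum())
    if n_nodata_counts:
        logger.info("%d in-county cells have nodata counts; weight set to 0",
                    n_nodata_counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.exp(b_cell) * np.power(t, a_cell)
    w = np.where(inside & np.isnan(a_cell), 1.0, w)   # fallback county: uniform
    w = np.where(inside & (np.isnan(t) | (t == 0)), 0.0, w)
    weights[inside] = w[inside]
    return GridRaster(zone_raster.spec, weights, units="weight")


def allocate_population(
    weights: GridRaster,
    zone_raster: ZoneRaster,
    stats: StatTable,
) -> tuple[GridRaster, AllocationDiagnostics]:
    """Redistribute county statistics over cells proportionally to weights.

    All-zero-weight counties fall back to uniform allocation.  A final
    renormalisation pass pins each county sum to its statistic.
    """
    if not weights.spec.approx_equal(zone_raster.spec):
        raise AllocationError("weight raster and zone raster grids do not match")
    labels = zone_raster.labels.ravel()
    w = np.where(np.isnan(weights.values.ravel()), 0.0, weights.values.ravel())
    if (w < 0).any():
        raise AllocationError("negative weights")
    nz = zone_raster.n_zones
    inside = labels >= 0
    zone_index = {zid: i for i, zid in enumerate(zone_raster.zone_ids)}
    missing = [zid for zid in stats.data["zone_id"] if zid not in zone_index]
    if missing:
        raise AllocationError(
            f"counties in stats absent from zone raster: {', '.join(missing)}"
        )
    n_cells = np.bincount(labels[inside], minlength=nz)
    wsum = np.bincount(labels[inside], weights=w[inside], minlength=nz)

    pop_cell = np.zeros(labels.size)
    rows = []
    for zid, target in zip(stats.data["zone_id"], stats.data["population"]):
        i = zone_index[zid]
        cells = np.flatnonzero(labels == i)
        if cells.size == 0:
            rows.append((zid, target, 0.0, 0, "no-cells"))
            logger.warning("county %s has no cells; population not allocated", zid)
            continue
        if wsum[i] > 0:
            alloc = target * w[cells] / wsum[i]
            fallback = ""
        else:
            alloc = np.full(cells.size, target / cells.size)
            fallback = "uniform"
            logger.info("county %s: all-zero weights, uniform fallback", zid)
        # renormalisation pass pins the county sum exactly
        s = alloc.sum()
        if s > 0:
            alloc *= target / s
        pop_cell[cells] = alloc
        rows.append((zid, target, float(alloc.sum()), int(cells.size), fallback))
    surface = np.full(labels.size, np.nan)
    surface[inside] = pop_cell[inside]
    diag = AllocationDiagnostics(
        pd.DataFrame(rows, columns=["zone_id", "target", "achieved", "n_cells", "fallback"])
    )
    raster = GridRaster(zone_raster.spec, surface.reshape(zone_raster.spec.shape),
                        units="persons")
    return raster, diag


def allocate_uniform(
    zone_raster: ZoneRaster, stats: StatTable
) -> tuple[GridRaster, AllocationDiagnostics]:
    """Uniform-areal baseline: each county's population spread evenly over its
    cells (the comparator for the weighted allocation)."""
    ones = GridRaster(
        zone_raster.spec, np.ones(zone_raster.spec.shape), units="weight"
    )
    return allocate_population(ones, zone_raster, stats)
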