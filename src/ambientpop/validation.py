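"""Accuracy assessment of an allocated population surface.

The protocol scores the surface against statistics for validation units finer
than the source counties (towns nested in counties): aggregate the surface to
the units, then compare estimate vs reference with mean squared error, the
squared Pearson correlation, and the through-origin least-squares slope of
reference on estimate.  Populations are divided by a configurable scale
(default 1e4 persons) before the MSE so its magnitude matches conventional
reporting for town-sized units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import GridRaster, StatTable
from .zonal import CountyTable, ZoneRaster

logger = logging.getLogger("ambientpop")

DEFAULT_POPULATION_SCALE = 1e4  # persons per reporting unit


class ValidationError(ValueError):
    pass


@dataclass
class ValidationReport:
    n_units: int
    mse: float
    r2: float | None           # squared Pearson correlation (None if undefined)
    slope: float               # through-origin slope of reference on estimate
    slope_with_intercept: float
    intercept: float
    population_scale: float
    table: pd.DataFrame        # unit_id, estimate, reference, error


def aggregate_to_units(
    surface: GridRaster, unit_raster: ZoneRaster
) -> pd.Series:
    """Sum the surface over each validation unit's cells (nodata counts 0)."""
    if not surface.spec.approx_equal(unit_raster.spec):
        raise ValidationError("surface and unit raster grids do not match")
    labels = unit_raster.labels.ravel()
    vals = np.where(np.isnan(surface.values.ravel()), 0.0, surface.values.ravel())
    inside = labels >= 0
    sums = np.bincount(labels[inside], weights=vals[inside],
                       minlength=unit_raster.n_zones)
    n_cells = np.bincount(labels[inside], minlength=unit_raster.n_zones)
    empty = [unit_raster.zone_ids[i] for i in np.flatnonzero(n_cells == 0)]
    if empty:
        logger.warning("%d validation units have zero cells", len(empty))
    return pd.Series(sums, index=pd.Index(unit_raster.zone_ids, name="unit_id"),
                     name="estimate")


def compare_to_reference(
    estimates: pd.Series,
    reference: StatTable | pd.Series,
    population_scale: float = DEFAULT_POPULATION_SCALE,
) -> ValidationReport:
    """Score unit-level estimates against reference statistics."""
    if population_scale <= 0:
        raise ValidationError("population_scale must be positive")
    if isinstance(reference, StatTable):
        ref = reference.data.set_index("zone_id")["population"]
    else:
        ref = reference
    common = estimates.index.intersection(ref.index)
    if len(common) != len(estimates) or len(common) != len(ref):
        logger.warning(
            "unit id mismatch: %d estimates, %d references, %d matched",
            len(estimates), len(ref), len(common),
        )
    if len(common) < 2:
        raise ValidationError("need at least 2 matched units")
    est = estimates.loc[common].to_numpy() / population_scale
    rf = ref.loc[common].to_numpy() / population_scale
    err = est - rf
    mse = float((err**2).mean())
    if np.std(est) == 0 or np.std(rf) == 0:
        logger.warning("zero variance in a series: R2 undefined")
        r2 = None
    else:
        r2 = float(np.corrcoef(est, rf)[0, 1] ** 2)
    denom = float((est**2).sum())
    slope = float((est * rf).sum() / denom) if denom > 0 else float("nan")
    # intercept-including fit reported for transparency
    if np.std(est) > 0:
        s_i, icpt = np.polyfit(est, rf, 1)
    else:
        s_i, icpt = float("nan"), float("nan")
    table = pd.DataFrame(
        {"unit_id": common, "estimate": est * population_scale,
         "reference": rf * population_scale,
         "error": err * population_scale}
    )
    return ValidationReport(
        n_units=len(common), mse=mse, r2=r2, slope=slope,
        slope_with_intercept=float(s_i), intercept=float(icpt),
        population_scale=population_scale, table=table,
    )


def correlation_analysis(table: CountyTable) -> tuple[float, float]:
    """Pearson correlation of county population vs aggregated count, on the
    raw and the ln-transformed pairs."""
    if len(table) < 3:
        raise ValidationError(f"need at least 3 counties, got {len(table)}")
    df = table.data
    pop = df["population"].to_numpy(dtype=float)
    lbs = df["lbs_total"].to_numpy(dtype=float)
    if np.std(pop) == 0 or np.std(lbs) == 0:
        raise ValidationError("constant series: correlation undefined")
    bad = df.loc[(df["population"] <= 0) | (df["lbs_total"] <= 0), "zone_id"].tolist()
    if bad:
        raise ValidationError(f"nonpositive values for zone(s): {bad}")
    r_raw = float(np.corrcoef(lbs, pop)[0, 1])
    r_log = float(np.corrcoef(np.log(lbs), np.log(pop))[0, 1])
    return r_raw, r_log
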