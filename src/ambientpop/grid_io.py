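"""Core grid and vector data types plus GeoTIFF / GeoJSON / CSV readers and writers.

All rasters live on a regular geographic (lon/lat, WGS84) grid described by a
:class:`GridSpec`.  Row 0 is the northernmost row and each cell covers the
half-open box ``[west, east) x (south, north]`` so that every point on a shared
edge belongs to exactly one cell.  In-memory rasters mark missing cells with
``NaN``; the spec's ``nodata`` sentinel is used only on disk.

GeoTIFF files are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, a minimal WGS84 GeoKey directory and
GDAL_NODATA) so they are readable by GDAL-based stacks.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger("ambientpop")

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORM = 34264
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class GridIOError(ValueError):
    """Raised for malformed raster/vector/table inputs."""


@dataclass(frozen=True)
class GridSpec:
    """Georeference of a regular lon/lat grid.

    ``origin_lon`` is the west edge of column 0 and ``origin_lat`` the north
    edge of row 0; ``cell_size`` is the uniform cell size in degrees.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GridIOError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridIOError(
                f"grid must have at least one row and column, got "
                f"{self.n_rows} x {self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Lon/lat of the center of cell (row, col)."""
        s = self.cell_size
        return (self.origin_lon + (col + 0.5) * s, self.origin_lat - (row + 0.5) * s)

    def cell_box(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) of the half-open box of cell (row, col)."""
        s = self.cell_size
        west = self.origin_lon + col * s
        north = self.origin_lat - row * s
        return (west, north - s, west + s, north)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized centers: (lon, lat) arrays each of shape (n_rows, n_cols)."""
        s = self.cell_size
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * s
        lat = self.origin_lat - (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(lon, lat)

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class GridRaster:
    """A 2-D value array with georeference.

    ``values`` uses NaN for nodata cells; ``units`` is a free-text tag such as
    "counts", "persons" or "weight".
    """

    spec: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise GridIOError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.spec.shape}"
            )
        if np.isinf(self.values).any():
            raise GridIOError("raster contains non-finite (inf) values")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return np.isnan(self.values)

    def copy(self) -> "GridRaster":
        return GridRaster(self.spec, self.values.copy(), self.units)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "GridRaster":
        return GridRaster(self.spec, values, self.units if units is None else units)


@dataclass
class Zone:
    zone_id: str
    geometry: BaseGeometry
    anchor: tuple[float, float]
    parent_id: str | None = None


@dataclass
class ZoneSet:
    """Polygon zones with unique string ids and anchor points."""

    zones: list[Zone] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise GridIOError(f"duplicate zone_id(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.zones)

    @property
    def zone_ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]


@dataclass
class StatTable:
    """Zone-level population statistics (zone_id -> permanent population)."""

    data: pd.DataFrame  # columns: zone_id (str), population (float)

    def __post_init__(self) -> None:
        df = self.data
        missing = {"zone_id", "population"} - set(df.columns)
        if missing:
            raise GridIOError(f"stat table missing column(s): {sorted(missing)}")
        df = df.copy()
        df["zone_id"] = df["zone_id"].astype(str)
        df["population"] = df["population"].astype(float)
        dupes = df.loc[df["zone_id"].duplicated(), "zone_id"].unique()
        if len(dupes):
            raise GridIOError(f"duplicate zone_id(s) in stats: {', '.join(dupes)}")
        if (df["population"] < 0).any():
            bad = df.loc[df["population"] < 0, "zone_id"].tolist()
            raise GridIOError(f"negative population for zone(s): {bad}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def population_of(self, zone_id: str) -> float:
        row = self.data.loc[self.data["zone_id"] == zone_id, "population"]
        if row.empty:
            raise KeyError(zone_id)
        return float(row.iloc[0])

    @property
    def total(self) -> float:
        return float(self.data["population"].sum())


# ---------------------------------------------------------------------------
# Raster I/O


def write_raster(raster: GridRaster, path: str | Path) -> None:
    """Write a GridRaster to a single-band georeferenced GeoTIFF (DEFLATE)."""
    spec = raster.spec
    path = Path(path)
    values = raster.values.copy()
    n_nodata = int(np.isnan(values).sum())
    if n_nodata == values.size:
        logger.warning("writing all-nodata raster to %s", path)
    values[np.isnan(values)] = spec.nodata
    s = spec.cell_size
    # GeoKeys: geographic model, PixelIsArea, WGS84
    geokeys = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)
    tifffile.imwrite(
        path,
        values,
        compression="zlib",
        extratags=[
            (_TAG_PIXEL_SCALE, 12, 3, (s, s, 0.0)),
            (_TAG_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, spec.origin_lon, spec.origin_lat, 0.0)),
            (_TAG_GEOKEYS, 3, len(geokeys), geokeys),
            (_TAG_GDAL_NODATA, 2, None, repr(spec.nodata)),
        ],
        metadata=None,
    )


def read_raster(path: str | Path, units: str = "") -> GridRaster:
    """Read a single-band geographic GeoTIFF into a GridRaster."""
    path = Path(path)
    if not path.exists():
        raise GridIOError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if len(tif.pages) > 1 or page.samplesperpixel > 1:
            raise GridIOError(f"multi-band raster not supported: {path}")
        values = page.asarray().astype(np.float64)
        if _TAG_TRANSFORM in page.tags:
            m = page.tags[_TAG_TRANSFORM].value
            if m[1] != 0.0 or m[4] != 0.0:
                raise GridIOError(f"rotated geotransform in {path}")
            sx, sy = m[0], -m[5]
            origin_lon, origin_lat = m[3], m[7]
        else:
            if _TAG_PIXEL_SCALE not in page.tags or _TAG_TIEPOINT not in page.tags:
                raise GridIOError(f"no geotransform (pixel scale / tiepoint) in {path}")
            sx, sy = page.tags[_TAG_PIXEL_SCALE].value[:2]
            tie = page.tags[_TAG_TIEPOINT].value
            origin_lon = tie[3] - tie[0] * sx
            origin_lat = tie[4] + tie[1] * sy
        if not math.isclose(sx, sy, rel_tol=0, abs_tol=1e-9):
            raise GridIOError(f"non-square cells ({sx} x {sy} degrees) in {path}")
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in page.tags:
            nodata = float(page.tags[_TAG_GDAL_NODATA].value)
    spec = GridSpec(
        origin_lon=float(origin_lon),
        origin_lat=float(origin_lat),
        cell_size=float(sx),
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        nodata=nodata,
    )
    values[values == nodata] = np.nan
    return GridRaster(spec, values, units=units)


# ---------------------------------------------------------------------------
# Vector / table I/O


def read_zones(
    path: str | Path,
    id_field: str = "zone_id",
    parent_field: str | None = None,
) -> ZoneSet:
    """Read polygon zones from a GeoJSON FeatureCollection.

    Invalid polygons are repaired with ``make_valid``; each zone's anchor
    defaults to the polygon centroid (representative point if the centroid
    falls outside the polygon).
    """
    path = Path(path)
    if not path.exists():
        raise GridIOError(f"zones file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    if not features:
        raise GridIOError(f"no features in {path}")
    zones: list[Zone] = []
    for feat in features:
        props = feat.get("properties", {})
        if id_field not in props:
            raise GridIOError(f"feature missing id field '{id_field}' in {path}")
        geom = geom_shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        anchor = _anchor_point(geom)
        parent = str(props[parent_field]) if parent_field and parent_field in props else None
        zones.append(Zone(str(props[id_field]), geom, anchor, parent))
    return ZoneSet(zones)


def _anchor_point(geom: BaseGeometry) -> tuple[float, float]:
    c = geom.centroid
    if not geom.covers(c):
        c = geom.representative_point()
    return (c.x, c.y)


def write_zones(zones: ZoneSet, path: str | Path, id_field: str = "zone_id") -> None:
    """Write a ZoneSet as a GeoJSON FeatureCollection."""
    features = []
    for z in zones.zones:
        props = {id_field: z.zone_id}
        if z.parent_id is not None:
            props["parent_id"] = z.parent_id
        features.append(
            {"type": "Feature", "properties": props, "geometry": geom_mapping(z.geometry)}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_stats(
    path: str | Path, id_field: str = "zone_id", pop_field: str = "population"
) -> StatTable:
    """Read a zone-level population CSV into a StatTable."""
    path = Path(path)
    if not path.exists():
        raise GridIOError(f"stats file not found: {path}")
    df = pd.read_csv(path, dtype={id_field: str})
    for col in (id_field, pop_field):
        if col not in df.columns:
            raise GridIOError(f"stats file {path} missing field '{col}'")
    return StatTable(df.rename(columns={id_field: "zone_id", pop_field: "population"}))


def write_stats(stats: StatTable, path: str | Path) -> None:
    stats.data.to_csv(path, index=False)


def join_diagnostics(zones: ZoneSet, stats: StatTable) -> dict[str, list[str]]:
    """Report zone ids without stats and stat rows without zones.

    Unmatched rows are reported, never silently dropped.
    """
    zone_ids = set(zones.zone_ids)
    stat_ids = set(stats.data["zone_id"])
    diag = {
        "zones_without_stats": sorted(zone_ids - stat_ids),
        "stats_without_zones": sorted(stat_ids - zone_ids),
    }
    for key, missing in diag.items():
        if missing:
            logger.warning("%s: %d (%s ...)", key, len(missing), ", ".join(missing[:5]))
    return diag
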