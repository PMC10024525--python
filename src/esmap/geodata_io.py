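"""Read, validate and align the gridded and vector inputs of the pipeline.

Rasters are single-band GeoTIFFs handled through :mod:`tifffile` with the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory and
GDAL_NODATA) written and parsed directly — land cover as unsigned 16-bit
integers, score surfaces as 32-bit floats with NaN nodata.  Zone polygons
travel as GeoJSON with ``zone_id``/``name``/``level``/``parent_id``
properties, legends as two-column CSV.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .errors import AlignmentError, ContractError, ValidationError

logger = logging.getLogger(__name__)

#: Mean-sphere radius used for geodesic pixel areas, km.
EARTH_RADIUS_KM = 6371.0072

#: CRS identifiers treated as geographic (degrees).
GEOGRAPHIC_CRS = frozenset({"EPSG:4326", "OGC:CRS84", "EPSG:4258"})

_REL_TOL = 1e-9

# GeoTIFF / GDAL tag codes.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

ZONE_LEVELS = ("national", "regional", "sub_regional")


# ---------------------------------------------------------------------------
# Grid


@dataclass(frozen=True, eq=False)
class Grid:
    """Geometry of a north-up regular raster grid.

    ``origin_x``/``origin_y`` locate the outer corner of pixel (0, 0);
    ``pixel_height`` is signed (negative for north-up grids).
    """

    crs_id: str
    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        if self.pixel_width == 0 or self.pixel_height == 0:
            raise ValidationError("pixel sizes must be non-zero")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_geographic(self) -> bool:
        return self.crs_id.upper() in GEOGRAPHIC_CRS

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_width

    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.pixel_height

    def row_edges(self) -> np.ndarray:
        """y coordinates of the n_rows + 1 horizontal cell edges."""
        return self.origin_y + np.arange(self.n_rows + 1) * self.pixel_height

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        if self.crs_id != other.crs_id:
            return False
        if (self.n_rows, self.n_cols) != (other.n_rows, other.n_cols):
            return False
        pairs = (
            (self.origin_x, other.origin_x),
            (self.origin_y, other.origin_y),
            (self.pixel_width, other.pixel_width),
            (self.pixel_height, other.pixel_height),
        )
        return all(
            math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=1e-12) for a, b in pairs
        )

    def __hash__(self) -> int:  # tolerance-based eq: hash on exact ints only
        return hash((self.crs_id, self.n_rows, self.n_cols))

    def describe_mismatch(self, other: "Grid") -> str | None:
        """Name the first differing field, or None if grids compare equal."""
        for name in (
            "crs_id", "n_rows", "n_cols",
            "origin_x", "origin_y", "pixel_width", "pixel_height",
        ):
            a, b = getattr(self, name), getattr(other, name)
            if isinstance(a, float):
                if not math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=1e-12):
                    return name
            elif a != b:
                return name
        return None


# ---------------------------------------------------------------------------
# Legend


@dataclass(frozen=True)
class Legend:
    """Ordered mapping of integer class codes to class names."""

    entries: tuple[tuple[int, str], ...]
    nodata_code: int = 0

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if len(codes) != len(set(codes)):
            raise ValidationError("legend class codes must be unique")
        if self.nodata_code in codes:
            raise ValidationError("nodata code must not be a legend class code")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def names(self) -> dict[int, str]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def code_index(self) -> dict[int, int]:
        return {c: i for i, c in enumerate(self.codes)}


def default_legend() -> Legend:
    """The 11-class legend used for the CGLC-style landscape."""
    return Legend(
        entries=(
            (20, "Shrubs"),
            (30, "Herbaceous vegetation"),
            (40, "Cultivated and managed vegetation/agriculture"),
            (50, "Urban/built up"),
            (60, "Bare/sparse vegetation"),
            (80, "Permanent water bodies"),
            (90, "Herbaceous wetland"),
            (114, "Closed forest, deciduous broad leaf"),
            (116, "Closed forest, other"),
            (124, "Open forest, deciduous broad leaf"),
            (126, "Open forest, other"),
        ),
        nodata_code=0,
    )


def read_legend(path: str | Path, nodata_code: int = 0) -> Legend:
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append((int(row["class_code"]), row["class_name"]))
    return Legend(entries=tuple(entries), nodata_code=nodata_code)


def write_legend(legend: Legend, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_code", "class_name"])
        writer.writerows(legend.entries)


# ---------------------------------------------------------------------------
# Land-cover raster


@dataclass
class LandCoverRaster:
    """One year of categorical land cover on a fixed grid."""

    grid: Grid
    year: int
    values: np.ndarray
    legend: Legend

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise TypeError("land cover values must be integers")
        if self.values.shape != self.grid.shape:
            raise AlignmentError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        allowed = set(self.legend.codes) | {self.legend.nodata_code}
        present = set(np.unique(self.values).tolist())
        extra = present - allowed
        if extra:
            raise ValidationError(f"values outside legend: {sorted(extra)}")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.legend.nodata_code

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.legend.nodata_code


# ---------------------------------------------------------------------------
# Zones


@dataclass(frozen=True)
class Zone:
    zone_id: str
    name: str
    level: str
    parent_id: str
    geometry: BaseGeometry


@dataclass
class ZoneSet:
    """Nested administrative zones (national / regional / sub_regional)."""

    zones: list[Zone]
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        if len(ids) != len(set(ids)):
            raise ValidationError("zone_ids must be unique")
        for z in self.zones:
            if z.level not in ZONE_LEVELS:
                raise ValidationError(f"unknown zone level {z.level!r}")
        regional_ids = {z.zone_id for z in self.zones if z.level == "regional"}
        for z in self.zones:
            if z.level == "sub_regional" and z.parent_id not in regional_ids:
                raise ValidationError(
                    f"sub-regional zone {z.zone_id} has no regional parent"
                )

    def at_level(self, level: str) -> list[Zone]:
        return [z for z in self.zones if z.level == level]

    def by_id(self, zone_id: str) -> Zone:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    def children(self, zone_id: str) -> list[Zone]:
        return [z for z in self.zones if z.parent_id == zone_id]

    def check_no_overlap(self, rel_tol: float = 1e-9) -> None:
        """Assert that geometries within each level have disjoint interiors."""
        for level in ZONE_LEVELS:
            zones = self.at_level(level)
            for i, a in enumerate(zones):
                for b in zones[i + 1:]:
                    inter = a.geometry.intersection(b.geometry).area
                    limit = rel_tol * max(a.geometry.area, b.geometry.area)
                    if inter > limit:
                        raise ValidationError(
                            f"zones {a.zone_id} and {b.zone_id} overlap "
                            f"(area {inter:g})"
                        )


def read_zones(path: str | Path) -> ZoneSet:
    """Read a ZoneSet from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    crs_id = doc.get("crs_id", "EPSG:4326")
    zones = []
    for feat in doc["features"]:
        props = feat["properties"]
        zones.append(
            Zone(
                zone_id=str(props["zone_id"]),
                name=str(props.get("name", props["zone_id"])),
                level=str(props["level"]),
                parent_id=str(props.get("parent_id") or ""),
                geometry=geom_shape(feat["geometry"]),
            )
        )
    return ZoneSet(zones=zones, crs_id=crs_id)


def write_zones(zones: ZoneSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "zone_id": z.zone_id,
                "name": z.name,
                "level": z.level,
                "parent_id": z.parent_id,
            },
            "geometry": geom_mapping(z.geometry),
        }
        for z in zones.zones
    ]
    doc = {"type": "FeatureCollection", "crs_id": zones.crs_id, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def zone_index_raster(
    zones: Sequence[Zone], grid: Grid
) -> np.ndarray:
    """Label each pixel with the index of the zone containing its center.

    Returns an int32 array shaped like the grid; pixels whose center falls in
    no zone get -1.  Later zones never overwrite earlier assignments, so for a
    valid (non-overlapping) level the order is irrelevant.
    """
    xs = grid.x_centers()
    ys = grid.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    out = np.full(grid.shape, -1, dtype=np.int32)
    for idx, zone in enumerate(zones):
        unassigned = out == -1
        if not unassigned.any():
            break
        hit = shapely.contains_xy(zone.geometry, xx[unassigned], yy[unassigned])
        rows, cols = np.nonzero(unassigned)
        out[rows[hit], cols[hit]] = idx
    return out


# ---------------------------------------------------------------------------
# Pixel areas


@dataclass(frozen=True)
class PixelAreaField:
    """Per-row pixel areas in km², nominal or spherical-geodesic."""

    mode: str
    nominal_area_km2: float = 0.0
    per_row_area_km2: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.mode not in ("nominal", "geodesic"):
            raise ValidationError(f"unknown area mode {self.mode!r}")
        if self.mode == "nominal" and self.nominal_area_km2 <= 0:
            raise ValidationError("nominal pixel area must be positive")
        if self.mode == "geodesic" and not (self.per_row_area_km2 > 0).all():
            raise ValidationError("geodesic pixel areas must be positive")

    def row_areas(self, n_rows: int) -> np.ndarray:
        """Vector of per-row pixel areas (length ``n_rows``)."""
        if self.mode == "nominal":
            return np.full(n_rows, self.nominal_area_km2)
        if len(self.per_row_area_km2) != n_rows:
            raise AlignmentError(
                f"area field has {len(self.per_row_area_km2)} rows, grid has {n_rows}"
            )
        return self.per_row_area_km2

    def area_raster(self, grid: Grid) -> np.ndarray:
        return np.broadcast_to(
            self.row_areas(grid.n_rows)[:, None], grid.shape
        )


def pixel_areas(
    grid: Grid, mode: str = "nominal", nominal_area_km2: float = 0.01
) -> PixelAreaField:
    """Build the pixel-area field for a grid.

    Geodesic mode uses the spherical zone formula
    ``A = R² · |Δλ| · |sin(φ_top) − sin(φ_bottom)|`` per row and requires a
    geographic CRS.
    """
    if mode == "nominal":
        return PixelAreaField(mode="nominal", nominal_area_km2=nominal_area_km2)
    if mode != "geodesic":
        raise ContractError(f"unknown area mode {mode!r}")
    if not grid.is_geographic:
        raise ContractError(
            f"geodesic areas require a geographic CRS, got {grid.crs_id!r}"
        )
    edges = np.radians(grid.row_edges())
    dlam = math.radians(abs(grid.pixel_width))
    per_row = (
        EARTH_RADIUS_KM ** 2 * dlam * np.abs(np.sin(edges[:-1]) - np.sin(edges[1:]))
    )
    return PixelAreaField(mode="geodesic", per_row_area_km2=per_row)


# ---------------------------------------------------------------------------
# Raster I/O


def _geo_extratags(grid: Grid, nodata: str) -> list[tuple]:
    scale = (abs(grid.pixel_width), abs(grid.pixel_height), 0.0)
    tie = (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)
    try:
        authority, code_s = grid.crs_id.split(":")
        code = int(code_s)
    except ValueError as exc:
        raise ValidationError(f"cannot encode CRS id {grid.crs_id!r}") from exc
    model = 2 if grid.is_geographic else 1
    crs_key = 2048 if grid.is_geographic else 3072
    geokeys = (
        1, 1, 0, 3,
        1024, 0, 1, model,     # GTModelType
        1025, 0, 1, 1,         # GTRasterType = PixelIsArea
        crs_key, 0, 1, code,
    )
    return [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tie, True),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys, True),
        (_TAG_GDAL_NODATA, "s", 0, nodata, True),
    ]


def _grid_from_tags(page, path: str | Path) -> tuple[Grid, float | None]:
    import tifffile

    tags = page.tags
    scale_tag = tags.get(_TAG_PIXEL_SCALE)
    tie_tag = tags.get(_TAG_TIEPOINT)
    if scale_tag is None or tie_tag is None:
        raise ValidationError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = scale_tag.value[0], scale_tag.value[1]
    tie = tie_tag.value
    # tie = (i, j, k, x, y, z): raster point (i, j) maps to model (x, y)
    origin_x = tie[3] - tie[0] * sx
    origin_y = tie[4] + tie[1] * sy
    crs_id = "EPSG:4326"
    keys_tag = tags.get(_TAG_GEO_KEYS)
    if keys_tag is not None:
        vals = keys_tag.value
        for i in range(4, len(vals), 4):
            key, _loc, _count, value = vals[i:i + 4]
            if key in (2048, 3072):
                crs_id = f"EPSG:{value}"
    nodata = None
    nd_tag = tags.get(_TAG_GDAL_NODATA)
    if nd_tag is not None:
        try:
            nodata = float(nd_tag.value)
        except ValueError:
            nodata = None
    n_rows, n_cols = page.shape
    grid = Grid(
        crs_id=crs_id,
        origin_x=origin_x,
        origin_y=origin_y,
        pixel_width=sx,
        pixel_height=-sy,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return grid, nodata


def read_landcover(path: str | Path, year: int, legend: Legend) -> LandCoverRaster:
    """Read a single-band integer GeoTIFF as one year of land cover.

    Values absent from the legend are remapped to the legend's nodata code;
    the number of remapped cells is reported through :mod:`warnings`.
    """
    import tifffile

    try:
        tf = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    with tf:
        page = tf.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValidationError(f"{path}: expected a single-band raster")
        if not np.issubdtype(values.dtype, np.integer):
            raise TypeError(
                f"{path}: land cover band must be integer, got {values.dtype}"
            )
        grid, file_nodata = _grid_from_tags(page, path)
    nodata = legend.nodata_code if file_nodata is None else int(file_nodata)
    values = values.astype(np.int64, copy=True)
    allowed = np.array(sorted(set(legend.codes) | {nodata}))
    known = np.isin(values, allowed)
    n_remapped = int((~known).sum())
    if n_remapped:
        warnings.warn(
            f"{path}: {n_remapped} cell(s) with codes outside the legend "
            f"remapped to nodata",
            stacklevel=2,
        )
        values[~known] = legend.nodata_code
    if nodata != legend.nodata_code:
        values[values == nodata] = legend.nodata_code
    return LandCoverRaster(grid=grid, year=year, values=values, legend=legend)


def write_landcover(lc: LandCoverRaster, path: str | Path) -> None:
    """Write land cover as a uint16 GeoTIFF with declared nodata."""
    import tifffile

    data = lc.values.astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        extratags=_geo_extratags(lc.grid, str(lc.legend.nodata_code)),
    )


def write_float_raster(values: np.ndarray, grid: Grid, path: str | Path) -> None:
    """Write a float surface (scores) as float32 GeoTIFF with NaN nodata."""
    import tifffile

    tifffile.imwrite(
        path,
        np.asarray(values, dtype=np.float32),
        extratags=_geo_extratags(grid, "nan"),
    )


def read_float_raster(path: str | Path) -> tuple[np.ndarray, Grid]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(np.float64)
        grid, _ = _grid_from_tags(page, path)
    return values, grid


# ---------------------------------------------------------------------------
# Clipping and series validation


def clip_to_boundary(
    lc: LandCoverRaster,
    boundary: BaseGeometry,
    boundary_crs: str | None = None,
) -> LandCoverRaster:
    """Mask pixels whose centers fall outside ``boundary`` to nodata.

    The grid extent is kept unchanged so every year in a series stays on an
    identical grid.
    """
    if boundary_crs is not None and boundary_crs != lc.grid.crs_id:
        raise ContractError(
            f"boundary CRS {boundary_crs!r} != raster CRS {lc.grid.crs_id!r}"
        )
    values = lc.values.copy()
    if boundary.is_empty:
        values[:] = lc.legend.nodata_code
    else:
        xs = lc.grid.x_centers()
        ys = lc.grid.y_centers()
        xx, yy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(boundary, xx, yy)
        values[~inside] = lc.legend.nodata_code
    return LandCoverRaster(
        grid=lc.grid, year=lc.year, values=values, legend=lc.legend
    )


def validate_series(rasters: Iterable[LandCoverRaster]) -> list[LandCoverRaster]:
    """Check a multi-year series shares one grid and legend; sort by year."""
    series = list(rasters)
    if len(series) < 2:
        raise ContractError("a series needs at least two yearly rasters")
    years = [lc.year for lc in series]
    if len(set(years)) != len(years):
        raise ContractError(f"duplicate years in series: {sorted(years)}")
    ref = series[0]
    for lc in series[1:]:
        mismatch = ref.grid.describe_mismatch(lc.grid)
        if mismatch is not None:
            raise AlignmentError(
                f"raster for year {lc.year} differs from year {ref.year} "
                f"in grid field {mismatch!r}"
            )
        if lc.legend != ref.legend:
            raise AlignmentError(
                f"raster for year {lc.year} uses a different legend"
            )
    return sorted(series, key=lambda lc: lc.year)
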