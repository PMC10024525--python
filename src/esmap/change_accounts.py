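"""Land-cover extent accounts: class areas, transitions, and change tables.

All quantities are areas in km², computed at full precision from pixel
counts weighted by the pixel-area field; rounding to whole km² happens only
in the CSV writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .errors import AlignmentError, ContractError
from .geodata_io import (
    LandCoverRaster,
    Legend,
    PixelAreaField,
    Zone,
    ZoneSet,
    zone_index_raster,
)

logger = logging.getLogger(__name__)

#: zone_id used for whole-raster accounts when no zones are supplied.
WHOLE_AREA_ZONE = "ALL"


@dataclass
class TransitionMatrix:
    """K×K area (km²) moved from row class (year_from) to column class."""

    year_from: int
    year_to: int
    legend: Legend
    cells: np.ndarray
    zone_id: str = WHOLE_AREA_ZONE
    excluded_nodata_km2: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.legend)
        self.cells = np.asarray(self.cells, dtype=np.float64)
        if self.cells.shape != (k, k):
            raise ContractError(
                f"cells must be {k}×{k} for a {k}-class legend"
            )
        if (self.cells < 0).any():
            raise ContractError("transition areas must be non-negative")

    @property
    def total_km2(self) -> float:
        return float(self.cells.sum())

    def row_sums(self) -> pd.Series:
        return pd.Series(self.cells.sum(axis=1), index=list(self.legend.codes))

    def col_sums(self) -> pd.Series:
        return pd.Series(self.cells.sum(axis=0), index=list(self.legend.codes))

    def to_frame(self) -> pd.DataFrame:
        codes = list(self.legend.codes)
        return pd.DataFrame(self.cells, index=codes, columns=codes)


def _class_area_vector(
    values: np.ndarray,
    select: np.ndarray,
    legend: Legend,
    area: np.ndarray,
) -> np.ndarray:
    """Summed area per legend class over the selected valid pixels."""
    k = len(legend)
    lut = np.full(int(max(legend.codes)) + 2, -1, dtype=np.int64)
    for i, code in enumerate(legend.codes):
        lut[code] = i
    idx = lut[values[select]]
    good = idx >= 0
    return np.bincount(idx[good], weights=area[select][good], minlength=k)


def class_areas(
    lc: LandCoverRaster,
    areas: PixelAreaField,
    zones: ZoneSet | None = None,
) -> pd.DataFrame:
    """Per-class (and per-zone) areas for one land-cover year.

    Returns a tidy frame with columns ``zone_id, level, year, class_code,
    area_km2``; nodata pixels are excluded.  Without zones a single
    pseudo-zone ``ALL`` covering the whole raster is reported.
    """
    area = areas.area_raster(lc.grid)
    valid = lc.valid_mask
    rows: list[dict] = []

    def emit(zone_id: str, level: str, select: np.ndarray) -> None:
        vec = _class_area_vector(lc.values, select, lc.legend, area)
        for code, a in zip(lc.legend.codes, vec):
            rows.append(
                {
                    "zone_id": zone_id,
                    "level": level,
                    "year": lc.year,
                    "class_code": code,
                    "area_km2": float(a),
                }
            )

    if zones is None:
        emit(WHOLE_AREA_ZONE, "national", valid)
    else:
        if zones.crs_id != lc.grid.crs_id:
            raise ContractError(
                f"zone CRS {zones.crs_id!r} != raster CRS {lc.grid.crs_id!r}"
            )
        for level in ("national", "regional", "sub_regional"):
            level_zones = zones.at_level(level)
            if not level_zones:
                continue
            zidx = zone_index_raster(level_zones, lc.grid)
            for i, zone in enumerate(level_zones):
                emit(zone.zone_id, level, valid & (zidx == i))
    return pd.DataFrame(rows)


def transition_matrix(
    lc_a: LandCoverRaster,
    lc_b: LandCoverRaster,
    areas: PixelAreaField,
    zone: BaseGeometry | Zone | None = None,
) -> TransitionMatrix:
    """Area moved between classes from ``lc_a`` to ``lc_b``.

    Pixels that are nodata in either year are excluded from the matrix and
    reported in ``excluded_nodata_km2``.
    """
    mismatch = lc_a.grid.describe_mismatch(lc_b.grid)
    if mismatch is not None:
        raise AlignmentError(f"rasters differ in grid field {mismatch!r}")
    if lc_a.legend != lc_b.legend:
        raise AlignmentError("rasters use different legends")
    if lc_a.year >= lc_b.year:
        raise ContractError("lc_a must precede lc_b in time")

    legend = lc_a.legend
    k = len(legend)
    area = areas.area_raster(lc_a.grid)

    zone_id = WHOLE_AREA_ZONE
    select = np.ones(lc_a.grid.shape, dtype=bool)
    if zone is not None:
        geom = zone.geometry if isinstance(zone, Zone) else zone
        if isinstance(zone, Zone):
            zone_id = zone.zone_id
        zidx = zone_index_raster(
            [Zone("z", "z", "national", "", geom)], lc_a.grid
        )
        select = zidx == 0

    both_valid = lc_a.valid_mask & lc_b.valid_mask
    excluded = float(area[select & ~both_valid].sum())
    select = select & both_valid

    lut = np.full(int(max(legend.codes)) + 2, -1, dtype=np.int64)
    for i, code in enumerate(legend.codes):
        lut[code] = i
    ia = lut[lc_a.values[select]]
    ib = lut[lc_b.values[select]]
    joint = ia * k + ib
    cells = np.bincount(joint, weights=area[select], minlength=k * k).reshape(k, k)
    if excluded:
        logger.info(
            "%s→%s %s: %.6g km² nodata-in-either-year excluded",
            lc_a.year, lc_b.year, zone_id, excluded,
        )
    return TransitionMatrix(
        year_from=lc_a.year,
        year_to=lc_b.year,
        legend=legend,
        cells=cells,
        zone_id=zone_id,
        excluded_nodata_km2=excluded,
    )


def net_change(tm: TransitionMatrix) -> pd.Series:
    """Signed net area change per class: column sum minus row sum."""
    return tm.col_sums() - tm.row_sums()


def change_table(
    series: Sequence[LandCoverRaster],
    baseline_year: int,
    areas: PixelAreaField,
    zones: ZoneSet | None = None,
) -> pd.DataFrame:
    """Net and percent change per class/year/zone relative to the baseline.

    ``percent_change`` is NA whenever the baseline area is zero.
    """
    years = [lc.year for lc in series]
    if baseline_year not in years:
        raise ContractError(f"baseline year {baseline_year} not in series {years}")
    frames = [class_areas(lc, areas, zones) for lc in series]
    all_areas = pd.concat(frames, ignore_index=True)
    base = (
        all_areas[all_areas["year"] == baseline_year]
        .set_index(["zone_id", "class_code"])["area_km2"]
    )
    out = all_areas.copy()
    key = pd.MultiIndex.from_frame(out[["zone_id", "class_code"]])
    baseline_area = base.reindex(key).to_numpy()
    out["net_change_km2"] = out["area_km2"] - baseline_area
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * out["net_change_km2"].to_numpy() / baseline_area
    pct[baseline_area == 0] = np.nan
    out["percent_change"] = pct
    return out


# ---------------------------------------------------------------------------
# CSV writers (whole-km² rounding happens here, not in the accounts)


def write_area_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["area_km2"] = out["area_km2"].round(6)
    out.to_csv(path, index=False)


def write_change_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in ("area_km2", "net_change_km2"):
        out[col] = out[col].round(6)
    out["percent_change"] = out["percent_change"].round(2)
    out.to_csv(path, index=False)


def write_transition_csv(tm: TransitionMatrix, path: str | Path) -> None:
    """Square-matrix CSV: first column from-class, header to-class codes."""
    frame = tm.to_frame()
    frame.index.name = "from_class"
    frame.to_csv(path)


def transitions_long_frame(matrices: Sequence[TransitionMatrix]) -> pd.DataFrame:
    rows = []
    for tm in matrices:
        codes = list(tm.legend.codes)
        for i, r in enumerate(codes):
            for j, c in enumerate(codes):
                rows.append(
                    {
                        "zone_id": tm.zone_id,
                        "year_from": tm.year_from,
                        "year_to": tm.year_to,
                        "from_class": r,
                        "to_class": c,
                        "area_km2": tm.cells[i, j],
                    }
                )
    return pd.DataFrame(rows)
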