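"""Equal-weight aggregation, zonal summaries and change reporting.

The overall supply-potential surface is the unweighted per-pixel sum of the
per-service score rasters, standardized to [0, 1]; zonal summaries are
area-weighted means and score·km² totals per zone, service, variant and
year, with changes reported against a baseline year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .es_scoring import ESRaster
from .geodata_io import Grid, PixelAreaField, ZoneSet, zone_index_raster

logger = logging.getLogger(__name__)

#: service_code used for the aggregate rows in summary tables.
OVERALL = "OVERALL"


@dataclass
class AggregateRaster:
    """Summed (raw) and min–max standardized overall supply surfaces."""

    grid: Grid
    variant: str
    year: int
    raw: np.ndarray
    standardized: np.ndarray
    n_services: int


def aggregate_overall(
    stack: Sequence[ESRaster], standardize: str = "minmax"
) -> AggregateRaster:
    """Sum one raster per service, then standardize.

    A pixel is valid only where every service has a score.  ``standardize``
    is ``"minmax"`` (default; an all-constant raw map standardizes to zeros)
    or ``"maxscore"`` (division by 5·n_services).
    """
    if not stack:
        raise ContractError("empty raster stack")
    if standardize not in ("minmax", "maxscore"):
        raise ContractError(f"unknown standardization {standardize!r}")
    ref = stack[0]
    codes = [r.service.code for r in stack]
    if len(set(codes)) != len(codes):
        raise ContractError(f"duplicate service in stack: {sorted(codes)}")
    for r in stack[1:]:
        if r.grid != ref.grid or r.variant != ref.variant or r.year != ref.year:
            raise ContractError("stack rasters must share grid, variant and year")
    raw = np.zeros(ref.grid.shape)
    valid = np.ones(ref.grid.shape, dtype=bool)
    for r in stack:
        valid &= np.isfinite(r.values)
        raw = raw + np.where(np.isfinite(r.values), r.values, 0.0)
    raw[~valid] = np.nan
    std = np.full(ref.grid.shape, np.nan)
    if valid.any():
        if standardize == "minmax":
            lo = np.nanmin(raw)
            hi = np.nanmax(raw)
            if hi > lo:
                std[valid] = (raw[valid] - lo) / (hi - lo)
            else:
                std[valid] = 0.0
        else:
            std[valid] = raw[valid] / (5.0 * len(stack))
    return AggregateRaster(
        grid=ref.grid,
        variant=ref.variant,
        year=ref.year,
        raw=raw,
        standardized=std,
        n_services=len(stack),
    )


def _zonal_rows(
    values: np.ndarray,
    grid: Grid,
    service_code: str,
    variant: str,
    year: int,
    zones: ZoneSet,
    areas: PixelAreaField,
) -> list[dict]:
    area = areas.area_raster(grid)
    finite = np.isfinite(values)
    rows = []
    for level in ("national", "regional", "sub_regional"):
        level_zones = zones.at_level(level)
        if not level_zones:
            continue
        zidx = zone_index_raster(level_zones, grid)
        for i, zone in enumerate(level_zones):
            sel = finite & (zidx == i)
            total_area = float(area[sel].sum())
            total = float((values[sel] * area[sel]).sum())
            mean = total / total_area if total_area > 0 else np.nan
            if total_area == 0:
                logger.warning("zone %s has no valid pixels", zone.zone_id)
            rows.append(
                {
                    "zone_id": zone.zone_id,
                    "level": level,
                    "service_code": service_code,
                    "variant": variant,
                    "year": year,
                    "mean_per_unit_area": mean,
                    "total_potential": total,
                    "valid_area_km2": total_area,
                }
            )
    return rows


def zonal_mean(
    raster: ESRaster | AggregateRaster,
    zones: ZoneSet,
    areas: PixelAreaField,
) -> pd.DataFrame:
    """Area-weighted zonal means and totals for one score surface.

    For an :class:`AggregateRaster` the standardized surface is summarized
    under the service code ``OVERALL_STD`` and the raw sum under
    ``OVERALL_RAW``.
    """
    if isinstance(raster, ESRaster):
        rows = _zonal_rows(
            raster.values, raster.grid, raster.service.code,
            raster.variant, raster.year, zones, areas,
        )
    else:
        rows = _zonal_rows(
            raster.raw, raster.grid, "OVERALL_RAW",
            raster.variant, raster.year, zones, areas,
        )
        rows += _zonal_rows(
            raster.standardized, raster.grid, "OVERALL_STD",
            raster.variant, raster.year, zones, areas,
        )
    return pd.DataFrame(rows)


def summary_table(
    stack: Sequence[ESRaster],
    zones: ZoneSet,
    areas: PixelAreaField,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Per-service zonal summary plus OVERALL rows.

    The OVERALL mean for a zone/variant/year is the unweighted mean of the
    per-service means; its total is the sum of the per-service totals.
    """
    frames = [zonal_mean(r, zones, areas) for r in stack]
    table = pd.concat(frames, ignore_index=True)
    if include_overall:
        keys = ["zone_id", "level", "variant", "year"]
        grouped = table.groupby(keys, sort=False)
        overall = grouped.agg(
            mean_per_unit_area=("mean_per_unit_area", "mean"),
            total_potential=("total_potential", "sum"),
            valid_area_km2=("valid_area_km2", "first"),
        ).reset_index()
        overall["service_code"] = OVERALL
        table = pd.concat([table, overall], ignore_index=True)
    return table


def summarize_changes(
    table: pd.DataFrame, baseline_year: int, target_year: int
) -> pd.DataFrame:
    """Change in zonal means between two years of a summary table.

    Keys present in only one year get an NA change and a warning.
    """
    keys = ["zone_id", "level", "service_code", "variant"]
    base = table[table["year"] == baseline_year].set_index(keys)
    target = table[table["year"] == target_year].set_index(keys)
    only = base.index.symmetric_difference(target.index)
    if len(only):
        logger.warning(
            "%d summary keys present in only one year; change reported as NA",
            len(only),
        )
    joined = target.join(
        base[["mean_per_unit_area", "total_potential"]],
        how="outer",
        lsuffix="", rsuffix="_baseline",
    ).reset_index()
    joined["change_vs_baseline"] = (
        joined["mean_per_unit_area"] - joined["mean_per_unit_area_baseline"]
    )
    joined["year"] = joined["year"].fillna(target_year).astype(int)
    joined["baseline_year"] = baseline_year
    return joined


def rank_services(
    table: pd.DataFrame, zone_id: str, year: int, variant: str
) -> list[str]:
    """Service codes sorted by zonal mean, descending; ties by code."""
    sel = table[
        (table["zone_id"] == zone_id)
        & (table["year"] == year)
        & (table["variant"] == variant)
        & (~table["service_code"].isin([OVERALL, "OVERALL_RAW", "OVERALL_STD"]))
    ]
    expected = 10
    if sel["service_code"].nunique() < expected:
        raise ContractError(
            f"summary for ({zone_id}, {year}, {variant}) has "
            f"{sel['service_code'].nunique()} services, expected {expected}"
        )
    ordered = sel.sort_values(
        ["mean_per_unit_area", "service_code"],
        ascending=[False, True],
        kind="mergesort",
    )
    return ordered["service_code"].tolist()


def round_for_report(table: pd.DataFrame) -> pd.DataFrame:
    """Apply presentation rounding: means/changes 2 dp, totals whole units."""
    out = table.copy()
    for col in ("mean_per_unit_area", "mean_per_unit_area_baseline", "change_vs_baseline"):
        if col in out.columns:
            out[col] = out[col].round(2)
    for col in ("total_potential", "total_potential_baseline"):
        if col in out.columns:
            out[col] = out[col].round(0)
    return out
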