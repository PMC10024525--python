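"""Ecosystem-service score matrices and raster reclassification.

The matrix approach attaches a 0–5 potential-supply score to every
(service, land-cover class) pair.  A consensus matrix carries the minimum,
arithmetic-mean and maximum score across the reviewed study matrices;
pairs no study reports are kept explicitly missing (NaN), never coerced
to zero.  Mapping a service is then a pure lookup reclassification of the
land-cover raster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, MappingError, ValidationError
from .geodata_io import Grid, LandCoverRaster, Legend

logger = logging.getLogger(__name__)

VARIANTS = ("min", "avg", "max")

SERVICE_GROUPS = ("provisioning", "regulating_maintenance", "cultural")


@dataclass(frozen=True)
class ESService:
    code: str
    name: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in SERVICE_GROUPS:
            raise ValidationError(f"unknown service group {self.group!r}")


def default_services() -> list[ESService]:
    """The ten-service registry (codes a–j)."""
    p, r, c = SERVICE_GROUPS
    return [
        ESService("a", "Crop provisioning", p),
        ESService("b", "Grazed biomass", p),
        ESService("c", "Wood supply", p),
        ESService("d", "Water supply", p),
        ESService("e", "Global climate regulation", r),
        ESService("f", "Soil and sediment retention", r),
        ESService("g", "Pollination", r),
        ESService("h", "Nursery population and habitat", r),
        ESService("i", "Recreation-related services", c),
        ESService("j", "Spiritual, artistic and symbolic services", c),
    ]


@dataclass
class StudyMatrix:
    """Scores assigned by one reviewed study: (service, class) → 0–5."""

    study_id: str
    scores: dict[tuple[str, int], float]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for (svc, cls), score in self.scores.items():
            if not (0.0 <= score <= 5.0):
                raise ValidationError(
                    f"study {self.study_id}: score {score} for "
                    f"(service {svc!r}, class {cls}) outside [0, 5]"
                )


@dataclass
class ESMatrix:
    """Consensus score table with min/avg/max variants per (service, class).

    ``table`` is indexed by (service_code, class_code) with columns
    ``min_score, avg_score, max_score, n_studies``; missing pairs have
    n_studies == 0 and NaN scores.
    """

    services: list[ESService]
    legend: Legend
    table: pd.DataFrame

    def __post_init__(self) -> None:
        covered = self.table[self.table["n_studies"] >= 1]
        bad = ~(
            (covered["min_score"] >= 0)
            & (covered["min_score"] <= covered["avg_score"])
            & (covered["avg_score"] <= covered["max_score"])
            & (covered["max_score"] <= 5)
        )
        if bad.any():
            raise ValidationError(
                f"matrix violates 0 ≤ min ≤ avg ≤ max ≤ 5 at {covered.index[bad].tolist()}"
            )

    def service(self, code: str) -> ESService:
        for svc in self.services:
            if svc.code == code:
                return svc
        raise KeyError(code)

    def lookup(self, service_code: str, variant: str) -> dict[int, float]:
        """class_code → score for one service/variant; missing pairs → NaN."""
        if variant not in VARIANTS:
            raise ContractError(f"unknown variant {variant!r}")
        col = f"{variant}_score"
        out = {}
        for cls in self.legend.codes:
            key = (service_code, cls)
            if key in self.table.index and self.table.loc[key, "n_studies"] >= 1:
                out[cls] = float(self.table.loc[key, col])
            else:
                out[cls] = float("nan")
        return out

    def to_long_frame(self) -> pd.DataFrame:
        names = {s.code: s.name for s in self.services}
        rows = []
        for (svc, cls), rec in self.table.iterrows():
            for variant in VARIANTS:
                rows.append(
                    {
                        "service_code": svc,
                        "service_name": names.get(svc, svc),
                        "class_code": cls,
                        "variant": variant,
                        "score": rec[f"{variant}_score"],
                        "n_studies": int(rec["n_studies"]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ESRaster:
    """Per-service potential-supply scores on the land-cover grid."""

    grid: Grid
    service: ESService
    variant: str
    year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ContractError("value array does not match grid shape")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and ((finite < 0).any() or (finite > 5).any()):
            raise ValidationError("scores must lie in [0, 5]")


# ---------------------------------------------------------------------------
# Consensus construction


def build_consensus_matrix(
    studies: Sequence[StudyMatrix],
    services: Sequence[ESService],
    legend: Legend,
) -> ESMatrix:
    """Min / arithmetic-mean / max over the studies reporting each pair."""
    if not studies:
        raise ContractError("need at least one study matrix")
    for study in studies:
        study.validate()
    index = pd.MultiIndex.from_product(
        [[s.code for s in services], list(legend.codes)],
        names=["service_code", "class_code"],
    )
    table = pd.DataFrame(
        {
            "min_score": np.nan,
            "avg_score": np.nan,
            "max_score": np.nan,
            "n_studies": 0,
        },
        index=index,
    )
    pooled: dict[tuple[str, int], list[float]] = {}
    for study in studies:
        for key, score in study.scores.items():
            if key in table.index:
                pooled.setdefault(key, []).append(score)
    for key, scores in pooled.items():
        table.loc[key, "min_score"] = min(scores)
        table.loc[key, "avg_score"] = sum(scores) / len(scores)
        table.loc[key, "max_score"] = max(scores)
        table.loc[key, "n_studies"] = len(scores)
    return ESMatrix(services=list(services), legend=legend, table=table)


def apply_crosswalk(
    study: StudyMatrix,
    class_map: Mapping,
    service_map: Mapping[str, str],
    merge: str = "mean",
) -> StudyMatrix:
    """Relabel a study's classes/services onto the target vocabularies.

    Source cells that collapse onto one target (service, class) pair are
    merged with the arithmetic mean by default (``merge="max"`` keeps the
    maximum instead).  Every populated source label must be mapped.
    """
    if merge not in ("mean", "max"):
        raise ContractError(f"unknown merge rule {merge!r}")
    missing_cls = sorted(
        {cls for (_, cls) in study.scores if cls not in class_map},
        key=str,
    )
    missing_svc = sorted(
        {svc for (svc, _) in study.scores if svc not in service_map}
    )
    if missing_cls or missing_svc:
        raise MappingError(
            f"study {study.study_id}: unmapped classes {missing_cls}, "
            f"unmapped services {missing_svc}"
        )
    grouped: dict[tuple[str, int], list[float]] = {}
    for (svc, cls), score in study.scores.items():
        target = (service_map[svc], class_map[cls])
        grouped.setdefault(target, []).append(score)
    merged = {}
    for target, scores in grouped.items():
        if len(scores) > 1:
            logger.info(
                "study %s: %d source cells merged into %s",
                study.study_id, len(scores), target,
            )
        merged[target] = (
            sum(scores) / len(scores) if merge == "mean" else max(scores)
        )
    return StudyMatrix(
        study_id=study.study_id, scores=merged, metadata=dict(study.metadata)
    )


# ---------------------------------------------------------------------------
# Reclassification


def score_raster(
    lc: LandCoverRaster,
    matrix: ESMatrix,
    service: ESService,
    variant: str,
) -> ESRaster:
    """Reclassify land cover into a per-service score surface.

    Nodata pixels stay nodata (NaN); classes with no study coverage become
    nodata and are logged.
    """
    if tuple(matrix.legend.codes) != tuple(lc.legend.codes):
        raise ContractError("land-cover legend does not match matrix classes")
    lookup = matrix.lookup(service.code, variant)
    missing = [cls for cls, v in lookup.items() if np.isnan(v)]
    if missing:
        logger.info(
            "service %s/%s: classes %s have no score, mapped to nodata",
            service.code, variant, missing,
        )
    lut = np.full(int(max(lc.legend.codes)) + 2, np.nan)
    for cls, score in lookup.items():
        lut[cls] = score
    out = np.full(lc.grid.shape, np.nan)
    valid = lc.valid_mask
    out[valid] = lut[lc.values[valid]]
    return ESRaster(
        grid=lc.grid, service=service, variant=variant, year=lc.year, values=out
    )


def score_stack(
    lc_by_year: Mapping[int, LandCoverRaster],
    matrix: ESMatrix,
    variants: Iterable[str],
    years: Iterable[int],
) -> list[ESRaster]:
    """One ESRaster per (service, variant, year)."""
    variants = list(variants)
    years = sorted(set(years))
    for variant in variants:
        if variant not in VARIANTS:
            raise ContractError(f"unknown variant {variant!r}")
    for year in years:
        if year not in lc_by_year:
            raise ContractError(f"no land-cover raster for year {year}")
    out = []
    for service in matrix.services:
        for variant in variants:
            for year in years:
                out.append(score_raster(lc_by_year[year], matrix, service, variant))
    return out


# ---------------------------------------------------------------------------
# CSV interchange (long format)


def write_matrix_csv(matrix: ESMatrix, path: str | Path) -> None:
    frame = matrix.to_long_frame()
    frame = frame[frame["n_studies"] >= 1]
    frame.to_csv(path, index=False)


def read_matrix_csv(
    path: str | Path,
    services: Sequence[ESService] | None = None,
    legend: Legend | None = None,
) -> ESMatrix:
    """Read a long-format score matrix CSV.

    When no registry/legend is supplied they are reconstructed from the file
    (service groups then default to the standard registry where codes match).
    """
    frame = pd.read_csv(path)
    required = {"service_code", "class_code", "variant", "score"}
    if not required <= set(frame.columns):
        raise ValidationError(f"matrix CSV must have columns {sorted(required)}")
    if services is None:
        known = {s.code: s for s in default_services()}
        services = []
        for code in frame["service_code"].unique():
            if "service_name" in frame.columns:
                name = str(
                    frame.loc[frame["service_code"] == code, "service_name"].iloc[0]
                )
            else:
                name = code
            services.append(
                known.get(code, ESService(code, name, "provisioning"))
            )
    if legend is None:
        codes = sorted(int(c) for c in frame["class_code"].unique())
        legend = Legend(entries=tuple((c, str(c)) for c in codes))
    index = pd.MultiIndex.from_product(
        [[s.code for s in services], list(legend.codes)],
        names=["service_code", "class_code"],
    )
    table = pd.DataFrame(
        {
            "min_score": np.nan,
            "avg_score": np.nan,
            "max_score": np.nan,
            "n_studies": 0,
        },
        index=index,
    )
    service_codes = {s.code for s in services}
    unknown_cls = sorted(
        set(frame["class_code"].astype(int)) - set(legend.codes)
    )
    unknown_svc = sorted(set(frame["service_code"].astype(str)) - service_codes)
    if unknown_cls or unknown_svc:
        raise ValidationError(
            f"{path}: matrix does not match legend/registry "
            f"(unknown classes {unknown_cls}, unknown services {unknown_svc})"
        )
    for _, row in frame.iterrows():
        key = (str(row["service_code"]), int(row["class_code"]))
        variant = str(row["variant"])
        if variant not in VARIANTS:
            raise ValidationError(f"unknown variant {variant!r} in {path}")
        table.loc[key, f"{variant}_score"] = float(row["score"])
        if "n_studies" in frame.columns:
            table.loc[key, "n_studies"] = int(row["n_studies"])
        else:
            table.loc[key, "n_studies"] = max(1, int(table.loc[key, "n_studies"]))
    # variants a file omits inherit the nearest provided one so the
    # min ≤ avg ≤ max invariant still holds
    filled = table[["min_score", "avg_score", "max_score"]]
    table["avg_score"] = filled["avg_score"].fillna(filled["max_score"]).fillna(filled["min_score"])
    table["min_score"] = filled["min_score"].fillna(table["avg_score"])
    table["max_score"] = filled["max_score"].fillna(table["avg_score"])
    return ESMatrix(services=list(services), legend=legend, table=table)


def read_study_matrices_csv(path: str | Path) -> list[StudyMatrix]:
    """Read per-study matrices from long CSV with a study_id column."""
    frame = pd.read_csv(path)
    studies = []
    for study_id, group in frame.groupby("study_id", sort=True):
        scores = {
            (str(r["service_code"]), int(r["class_code"])): float(r["score"])
            for _, r in group.iterrows()
        }
        studies.append(StudyMatrix(study_id=str(study_id), scores=scores))
    return studies


def write_study_matrices_csv(studies: Sequence[StudyMatrix], path: str | Path) -> None:
    rows = []
    for study in studies:
        for (svc, cls), score in sorted(study.scores.items()):
            rows.append(
                {
                    "study_id": study.study_id,
                    "service_code": svc,
                    "class_code": cls,
                    "score": score,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
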