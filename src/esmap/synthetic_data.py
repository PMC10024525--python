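"""Synthetic landscapes, nested zones and study matrices with ground truth.

Landscapes are nearest-seed (Voronoi) patch mosaics so that classes show
spatial autocorrelation like real land cover; year-to-year change follows a
known per-pixel Markov transition matrix so recovery tests have an exact
target.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree
from shapely.geometry import box

from .errors import ContractError, ValidationError
from .es_scoring import ESService, StudyMatrix, default_services
from .geodata_io import Grid, Legend, LandCoverRaster, Zone, ZoneSet, default_legend

# sub-seed offsets so one scenario seed reproduces each component alone
_SEED_LANDSCAPE = 1
_SEED_TRANSITION = 2
_SEED_ZONES = 3
_SEED_STUDIES = 4

#: class shares mirroring the dominant CGLC-like landscape composition
DEFAULT_PROPORTIONS: dict[int, float] = {
    20: 0.266,
    30: 0.173,
    40: 0.056,
    50: 0.001,
    60: 0.497,
    80: 0.002,
    90: 0.001,
    114: 0.001,
    116: 0.001,
    124: 0.001,
    126: 0.001,
}


def default_grid(n_rows: int = 500, n_cols: int = 500) -> Grid:
    """Projected 100 m grid (nominal pixel area 0.01 km²)."""
    return Grid(
        crs_id="EPSG:32637",
        origin_x=500000.0,
        origin_y=1700000.0,
        pixel_width=100.0,
        pixel_height=-100.0,
        n_rows=n_rows,
        n_cols=n_cols,
    )


@dataclass
class LandscapeConfig:
    grid: Grid
    class_proportions: dict[int, float]
    n_patches: int
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValidationError("class proportions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, not 1")
        if not (1 <= self.n_patches <= self.grid.n_rows * self.grid.n_cols):
            raise ValidationError("n_patches must be in [1, n_pixels]")


@dataclass
class MarkovTransitions:
    """Row-stochastic one-step class transition probabilities."""

    P: np.ndarray
    codes: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        k = len(self.codes)
        if self.P.shape != (k, k):
            raise ValidationError(f"P must be {k}×{k}")
        if ((self.P < 0) | (self.P > 1)).any():
            raise ValidationError("transition probabilities must be in [0, 1]")
        bad = np.abs(self.P.sum(axis=1) - 1.0) > 1e-9
        if bad.any():
            raise ValidationError(
                f"rows {np.nonzero(bad)[0].tolist()} of P do not sum to 1"
            )


def identity_transitions(legend: Legend, seed: int = 0) -> MarkovTransitions:
    k = len(legend)
    return MarkovTransitions(P=np.eye(k), codes=legend.codes, seed=seed)


def greening_transitions(
    legend: Legend, bare_to_herb: float = 0.08, seed: int = 0
) -> MarkovTransitions:
    """Mostly-persistent transitions with a dominant bare→herbaceous flow."""
    k = len(legend)
    P = np.eye(k)
    idx = legend.code_index()
    P[idx[60], idx[60]] = 1.0 - bare_to_herb
    P[idx[60], idx[30]] = bare_to_herb
    return MarkovTransitions(P=P, codes=legend.codes, seed=seed)


def generate_landscape(cfg: LandscapeConfig, legend: Legend | None = None) -> LandCoverRaster:
    """Voronoi patch mosaic with classes sampled from the configured shares."""
    if legend is None:
        legend = default_legend()
    rng = np.random.default_rng(cfg.seed + _SEED_LANDSCAPE)
    grid = cfg.grid
    # seed points in pixel coordinates
    pts = rng.uniform(
        low=(0.0, 0.0),
        high=(grid.n_rows, grid.n_cols),
        size=(cfg.n_patches, 2),
    )
    codes = np.array(sorted(cfg.class_proportions))
    probs = np.array([cfg.class_proportions[c] for c in codes])
    patch_class = rng.choice(codes, size=cfg.n_patches, p=probs)
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows) + 0.5, np.arange(grid.n_cols) + 0.5, indexing="ij"
    )
    centers = np.column_stack([rows.ravel(), cols.ravel()])
    _, nearest = cKDTree(pts).query(centers, k=1)
    values = patch_class[nearest].reshape(grid.shape)
    return LandCoverRaster(grid=grid, year=0, values=values, legend=legend)


def apply_transitions(
    lc: LandCoverRaster, mt: MarkovTransitions
) -> LandCoverRaster:
    """Draw each pixel's next class independently from its P row.

    Nodata pixels are left unchanged; the result is deterministic for a
    given ``mt.seed``.
    """
    if tuple(mt.codes) != tuple(lc.legend.codes):
        raise ContractError("transition matrix classes do not match legend")
    rng = np.random.default_rng(mt.seed + _SEED_TRANSITION)
    values = lc.values.copy()
    codes = np.array(mt.codes)
    # one uniform draw per pixel; inverse-CDF against the pixel's P row
    u = rng.random(lc.grid.shape)
    for i, code in enumerate(mt.codes):
        sel = lc.values == code
        if not sel.any():
            continue
        cdf = np.cumsum(mt.P[i])
        cdf[-1] = 1.0
        nxt = np.searchsorted(cdf, u[sel], side="left")
        values[sel] = codes[nxt]
    values[lc.nodata_mask] = lc.legend.nodata_code
    return LandCoverRaster(
        grid=lc.grid, year=lc.year + 1, values=values, legend=lc.legend
    )


def _split_sizes(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def generate_zones(
    grid: Grid, n_regions: int, subs_per_region: int, seed: int = 0
) -> ZoneSet:
    """Rectangular nested tiling: column-strip regions, row-strip sub-regions.

    Zone edges coincide with pixel edges, so pixel centers are never on a
    shared boundary and the zones tile the extent exactly.
    """
    if n_regions * subs_per_region < 1:
        raise ContractError("need at least one zone")
    if n_regions > grid.n_cols or subs_per_region > grid.n_rows:
        raise ContractError("more zones than pixel rows/columns")
    x0, y0 = grid.origin_x, grid.origin_y
    x1 = x0 + grid.n_cols * grid.pixel_width
    y1 = y0 + grid.n_rows * grid.pixel_height
    national = box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))
    zones = [Zone("NAT", "National", "national", "", national)]
    col_sizes = _split_sizes(grid.n_cols, n_regions)
    col_edges = np.concatenate([[0], np.cumsum(col_sizes)])
    row_sizes = _split_sizes(grid.n_rows, subs_per_region)
    row_edges = np.concatenate([[0], np.cumsum(row_sizes)])
    for r in range(n_regions):
        rx0 = x0 + col_edges[r] * grid.pixel_width
        rx1 = x0 + col_edges[r + 1] * grid.pixel_width
        ry0, ry1 = y0, y1
        region_id = f"R{r + 1:02d}"
        zones.append(
            Zone(
                region_id,
                f"Region {r + 1}",
                "regional",
                "NAT",
                box(min(rx0, rx1), min(ry0, ry1), max(rx0, rx1), max(ry0, ry1)),
            )
        )
        for s in range(subs_per_region):
            sy0 = y0 + row_edges[s] * grid.pixel_height
            sy1 = y0 + row_edges[s + 1] * grid.pixel_height
            zones.append(
                Zone(
                    f"{region_id}S{s + 1:02d}",
                    f"Sub-region {r + 1}.{s + 1}",
                    "sub_regional",
                    region_id,
                    box(min(rx0, rx1), min(sy0, sy1), max(rx0, rx1), max(sy0, sy1)),
                )
            )
    return ZoneSet(zones=zones, crs_id=grid.crs_id)


def generate_study_matrices(
    n_studies: int,
    services: Sequence[ESService] | None = None,
    legend: Legend | None = None,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> tuple[list[StudyMatrix], dict[tuple[str, int], tuple[float, float, float]]]:
    """Literature-style study matrices around a latent integer score.

    Each study perturbs the latent score with Gaussian noise, rounds to the
    nearest integer and clips to [0, 5].  Returns the studies together with
    the exact per-pair (min, avg, max) consensus computed directly from the
    generated scores.
    """
    if n_studies < 1:
        raise ContractError("need at least one study")
    if services is None:
        services = default_services()
    if legend is None:
        legend = default_legend()
    rng = np.random.default_rng(seed + _SEED_STUDIES)
    pairs = [(s.code, c) for s in services for c in legend.codes]
    latent = {p: int(rng.integers(0, 6)) for p in pairs}
    studies = []
    for i in range(n_studies):
        scores = {}
        for p in pairs:
            val = latent[p] + rng.normal(0.0, noise_sd)
            scores[p] = float(min(5, max(0, round(val))))
        studies.append(
            StudyMatrix(study_id=f"study_{i + 1:02d}", scores=scores)
        )
    consensus: dict[tuple[str, int], tuple[float, float, float]] = {}
    for p in pairs:
        vals = [st.scores[p] for st in studies]
        consensus[p] = (min(vals), sum(vals) / len(vals), max(vals))
    return studies, consensus


# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass
class Scenario:
    """A full synthetic experiment: landscape, transitions, zones, studies."""

    grid: Grid
    class_proportions: dict[int, float]
    n_patches: int = 2000
    years: tuple[int, ...] = (2015, 2016)
    transitions: MarkovTransitions | None = None
    n_regions: int = 6
    subs_per_region: int = 10
    n_studies: int = 8
    noise_sd: float = 0.8
    seed: int = 0
    legend: Legend = field(default_factory=default_legend)

    def landscape_config(self) -> LandscapeConfig:
        return LandscapeConfig(
            grid=self.grid,
            class_proportions=self.class_proportions,
            n_patches=self.n_patches,
            seed=self.seed,
        )


def default_scenario(seed: int = 0, n_rows: int = 500, n_cols: int = 500) -> Scenario:
    legend = default_legend()
    n_patches = min(2000, max(1, (n_rows * n_cols) // 125))
    return Scenario(
        grid=default_grid(n_rows, n_cols),
        class_proportions=dict(DEFAULT_PROPORTIONS),
        n_patches=n_patches,
        transitions=greening_transitions(legend, seed=seed),
        seed=seed,
        legend=legend,
    )


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from YAML; unspecified fields use the defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    seed = int(doc.get("seed", 0))
    legend = default_legend()
    grid_doc = doc.get("grid", {})
    grid = default_grid(
        n_rows=int(grid_doc.get("n_rows", 500)),
        n_cols=int(grid_doc.get("n_cols", 500)),
    )
    proportions = {
        int(k): float(v)
        for k, v in doc.get("class_proportions", DEFAULT_PROPORTIONS).items()
    }
    transitions = None
    if "transitions" in doc:
        codes = legend.codes
        idx = legend.code_index()
        P = np.eye(len(codes))
        for from_code, row in doc["transitions"].items():
            i = idx[int(from_code)]
            P[i] = 0.0
            for to_code, prob in row.items():
                P[i, idx[int(to_code)]] = float(prob)
        transitions = MarkovTransitions(P=P, codes=codes, seed=seed)
    else:
        transitions = greening_transitions(legend, seed=seed)
    years = tuple(int(y) for y in doc.get("years", (2015, 2016)))
    return Scenario(
        grid=grid,
        class_proportions=proportions,
        n_patches=int(doc.get("n_patches", 2000)),
        years=years,
        transitions=transitions,
        n_regions=int(doc.get("n_regions", 6)),
        subs_per_region=int(doc.get("subs_per_region", 10)),
        n_studies=int(doc.get("n_studies", 8)),
        noise_sd=float(doc.get("noise_sd", 0.8)),
        seed=seed,
        legend=legend,
    )


def run_scenario(
    scenario: Scenario,
) -> tuple[list[LandCoverRaster], ZoneSet, list[StudyMatrix], dict]:
    """Generate the full synthetic dataset plus a ground-truth record."""
    lc0 = generate_landscape(scenario.landscape_config(), scenario.legend)
    series = []
    lc = LandCoverRaster(
        grid=lc0.grid,
        year=scenario.years[0],
        values=lc0.values,
        legend=scenario.legend,
    )
    series.append(lc)
    mt = scenario.transitions or identity_transitions(scenario.legend, scenario.seed)
    for step, year in enumerate(scenario.years[1:]):
        stepped = MarkovTransitions(P=mt.P, codes=mt.codes, seed=mt.seed + 1000 * (step + 1))
        nxt = apply_transitions(series[-1], stepped)
        series.append(
            LandCoverRaster(
                grid=nxt.grid, year=year, values=nxt.values, legend=scenario.legend
            )
        )
    zones = generate_zones(
        scenario.grid, scenario.n_regions, scenario.subs_per_region, scenario.seed
    )
    studies, consensus = generate_study_matrices(
        scenario.n_studies,
        legend=scenario.legend,
        noise_sd=scenario.noise_sd,
        seed=scenario.seed,
    )
    truth = {
        "seed": scenario.seed,
        "class_proportions": {str(k): v for k, v in scenario.class_proportions.items()},
        "transition_matrix": {
            "codes": list(mt.codes),
            "P": mt.P.tolist(),
        },
        "consensus": {
            f"{svc}:{cls}": {"min": mn, "avg": av, "max": mx}
            for (svc, cls), (mn, av, mx) in consensus.items()
        },
        "years": list(scenario.years),
    }
    return series, zones, studies, truth
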