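"""Grid-cell mean species abundance under multiplicative pressures.

Three pressure layers — land use (table lookup), infrastructure (distance
bands around roads) and habitat fragmentation (patch-area response on
natural classes) — multiply into a total MSA in [0, 1].  The cocoa
counterfactual replaces cocoa cells with primary forest and differences the
two scenarios.

Shipped parameter defaults are documented, overridable configuration; they
follow published GLOBIO-class response tables in structure and ordering but
are not a bit-exact clone of any GLOBIO release.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import yaml
from scipy import ndimage
from shapely.geometry import LineString
from shapely.ops import unary_union

from bioscape.geodata_io import ContinuousRaster, GeodataError, GridSpec
from bioscape.landuse_harmonizer import LU, LANDUSE_LEGEND, LandUseRaster

logger = logging.getLogger("bioscape.msa_model")

DEFAULT_MSA_LU = {
    "primary_forest": 1.0,
    "lightly_used_natural_forest": 0.7,
    "secondary_forest": 0.5,
    "plantation_forest": 0.2,
    "primary_vegetation": 1.0,
    "low_input_agriculture": 0.3,
    "agroforestry": 0.5,
    "pasture": 0.3,
    "built_up": 0.05,
}

#: (max_distance_m, multiplier); a cell at distance d gets the first band with
#: max_distance > d (half-open [d_{k-1}, d_k)), 1.0 beyond the last band.
DEFAULT_ROAD_BANDS = [(500.0, 0.8), (1500.0, 0.9), (5000.0, 0.95)]

#: (patch_area_ha, multiplier) breakpoints, piecewise-linear in log10(area),
#: clamped at the ends (saturates at 1).
DEFAULT_FRAG_RESPONSE = [
    (1.0, 0.35),
    (10.0, 0.55),
    (100.0, 0.70),
    (1_000.0, 0.85),
    (10_000.0, 0.95),
    (100_000.0, 1.0),
]

DEFAULT_NATURAL_CLASSES = (
    "primary_forest",
    "lightly_used_natural_forest",
    "secondary_forest",
    "primary_vegetation",
)


@dataclass(frozen=True)
class MSAParams:
    """All pressure-response tables."""

    msa_lu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MSA_LU))
    road_bands: tuple[tuple[float, float], ...] = tuple(DEFAULT_ROAD_BANDS)
    frag_response: tuple[tuple[float, float], ...] = tuple(DEFAULT_FRAG_RESPONSE)
    natural_classes: tuple[str, ...] = DEFAULT_NATURAL_CLASSES

    def __post_init__(self) -> None:
        for name, v in self.msa_lu.items():
            if not 0.0 <= v <= 1.0:
                raise GeodataError(f"msa_lu[{name}] must be in [0,1], got {v}")
        if self.msa_lu.get("primary_forest") != 1.0:
            raise GeodataError("msa_lu[primary_forest] must be 1.0 (reference state)")
        dists = [d for d, _ in self.road_bands]
        mults = [m for _, m in self.road_bands]
        if any(b <= a for a, b in zip(dists, dists[1:])):
            raise GeodataError("road band distances must be strictly increasing")
        if any(not 0.0 <= m <= 1.0 for m in mults):
            raise GeodataError("road band multipliers must be in [0,1]")
        if any(b < a for a, b in zip(mults, mults[1:])):
            raise GeodataError("road band multipliers must be non-decreasing")
        areas = [a for a, _ in self.frag_response]
        fmult = [m for _, m in self.frag_response]
        if any(b <= a for a, b in zip(areas, areas[1:])) or any(a <= 0 for a in areas):
            raise GeodataError("frag_response areas must be positive and strictly increasing")
        if any(not 0.0 <= m <= 1.0 for m in fmult):
            raise GeodataError("frag multipliers must be in [0,1]")
        if any(b < a for a, b in zip(fmult, fmult[1:])):
            raise GeodataError("frag_response must be non-decreasing in area")
        if not self.natural_classes:
            raise GeodataError("natural_classes must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MSAParams":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            msa_lu=dict(raw["msa_lu"]),
            road_bands=tuple((float(d), float(m)) for d, m in raw["road_bands"]),
            frag_response=tuple((float(a), float(m)) for a, m in raw["frag_response"]),
            natural_classes=tuple(raw["natural_classes"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "msa_lu": self.msa_lu,
                    "road_bands": [list(b) for b in self.road_bands],
                    "frag_response": [list(b) for b in self.frag_response],
                    "natural_classes": list(self.natural_classes),
                }
            ),
            encoding="utf-8",
        )


@dataclass
class MSALayers:
    msa_lu: ContinuousRaster
    msa_infra: ContinuousRaster
    msa_frag: ContinuousRaster
    msa_total: ContinuousRaster


def msa_landuse(landuse: LandUseRaster, params: MSAParams) -> ContinuousRaster:
    """Pure per-cell table lookup of land-use MSA."""
    codes = landuse.landuse.codes
    lut = np.full(max(LANDUSE_LEGEND) + 1, np.nan)
    for code, name in LANDUSE_LEGEND.items():
        if name not in params.msa_lu:
            raise GeodataError(f"msa_lu has no entry for land-use class {name!r}")
        lut[code] = params.msa_lu[name]
    present = np.unique(codes[landuse.landuse.valid_mask])
    unknown = [c for c in present.tolist() if c not in LANDUSE_LEGEND]
    if unknown:
        raise GeodataError(f"unknown land-use codes {unknown}")
    values = np.full(codes.shape, np.nan)
    valid = landuse.landuse.valid_mask
    values[valid] = lut[codes[valid]]
    return ContinuousRaster(grid=landuse.grid, values=values)


def road_distances(roads: Sequence[LineString], grid: GridSpec) -> np.ndarray:
    """Euclidean distance from every cell centre to the nearest road (metres)."""
    cx, cy = grid.cell_centers()
    if not roads:
        return np.full(grid.shape, np.inf)
    merged = unary_union(list(roads))
    pts = shapely.points(cx.ravel(), cy.ravel())
    return shapely.distance(pts, merged).reshape(grid.shape)


def msa_infrastructure(
    landuse: LandUseRaster, roads: Sequence[LineString], params: MSAParams
) -> ContinuousRaster:
    """Distance-band road-disturbance multiplier; built-up cells get 1.0
    (their pressure is already in the land-use term)."""
    grid = landuse.grid
    dist = road_distances(roads, grid)
    band_edges = np.array([d for d, _ in params.road_bands])
    band_mults = np.array([m for _, m in params.road_bands] + [1.0])
    idx = np.searchsorted(band_edges, dist, side="right")
    values = band_mults[idx]
    values[landuse.class_mask("built_up")] = 1.0
    values[~landuse.landuse.valid_mask] = np.nan
    return ContinuousRaster(grid=grid, values=values)


def patch_areas(natural_mask: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Per-cell area (ha) of the 4-connected natural patch; NaN off-patch."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(natural_mask, structure=structure)
    out = np.full(natural_mask.shape, np.nan)
    if n:
        counts = np.bincount(labels.ravel())
        on = natural_mask
        out[on] = counts[labels[on]] * grid.cell_area_ha
    return out


def frag_multiplier(area_ha: np.ndarray, params: MSAParams) -> np.ndarray:
    """Piecewise-linear fragmentation response in log10(patch area)."""
    xp = np.log10([a for a, _ in params.frag_response])
    fp = [m for _, m in params.frag_response]
    return np.interp(np.log10(area_ha), xp, fp)


def msa_fragmentation(landuse: LandUseRaster, params: MSAParams) -> ContinuousRaster:
    """Patch-area fragmentation multiplier on natural-class cells, 1.0 elsewhere."""
    grid = landuse.grid
    natural = landuse.class_mask(*params.natural_classes)
    values = np.ones(grid.shape)
    if natural.any():
        areas = patch_areas(natural, grid)
        values[natural] = frag_multiplier(areas[natural], params)
    values[~landuse.landuse.valid_mask] = np.nan
    return ContinuousRaster(grid=grid, values=values)


def compute_msa(
    landuse: LandUseRaster, roads: Sequence[LineString], params: MSAParams
) -> MSALayers:
    """Total MSA = land-use × infrastructure × fragmentation, cellwise."""
    lu = msa_landuse(landuse, params)
    infra = msa_infrastructure(landuse, roads, params)
    frag = msa_fragmentation(landuse, params)
    total = ContinuousRaster(grid=landuse.grid, values=lu.values * infra.values * frag.values)
    return MSALayers(msa_lu=lu, msa_infra=infra, msa_frag=frag, msa_total=total)


def counterfactual_landuse(landuse: LandUseRaster) -> LandUseRaster:
    """Precultivation reference: cocoa cells become primary forest."""
    codes = landuse.landuse.codes.copy()
    codes[landuse.cocoa_mask] = LU["primary_forest"]
    lu = replace(landuse.landuse, codes=codes)
    return LandUseRaster(
        landuse=lu,
        cocoa_mask=np.zeros(landuse.grid.shape, dtype=bool),
        cocoa_type=np.zeros(landuse.grid.shape, dtype=np.int8),
    )


def msa_loss_cocoa(
    landuse: LandUseRaster, roads: Sequence[LineString], params: MSAParams
) -> ContinuousRaster:
    """MSA_nv − MSA, clamped below at 0; reported on all cells.

    Roads are retained in the counterfactual (only land use changes) — a
    logged assumption.  Negative differences (fragmentation edge effects of
    the counterfactual) are clamped and counted.
    """
    logger.info("counterfactual retains the road network; only land use changes")
    actual = compute_msa(landuse, roads, params).msa_total.values
    reference = compute_msa(counterfactual_landuse(landuse), roads, params).msa_total.values
    diff = reference - actual
    n_neg = int(np.nansum(diff < 0))
    if n_neg:
        logger.info("msa_loss_cocoa: clamped %d negative-loss cells to 0", n_neg)
    return ContinuousRaster(grid=landuse.grid, values=np.clip(diff, 0.0, None))
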