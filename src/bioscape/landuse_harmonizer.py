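"""Priority-ordered allocation of the base land cover into nine land-use classes.

Allocation order (later steps never overwrite earlier ones):

1. cocoa cells, typed full-sun/agroforestry -> low_input_agriculture / agroforestry
2. remaining agriculture cells -> low_input_agriculture or agroforestry per hint
3. pasture: greedy highest-suitability fill of herbaceous/shrub cells up to an
   area budget
4. forest cells -> primary/plantation (management layer) then lightly-used vs
   secondary (integrity threshold)
5. remaining vegetated cells -> primary_vegetation
6. bare/infrastructure -> built_up; water stays nodata
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from bioscape.geodata_io import (
    CategoricalRaster,
    ContinuousRaster,
    GeodataError,
    GridSpec,
    RunConfig,
    log_area,
)
from bioscape.synthetic_landscape import LandscapeBundle

logger = logging.getLogger("bioscape.landuse_harmonizer")

LANDUSE_LEGEND = {
    1: "primary_forest",
    2: "lightly_used_natural_forest",
    3: "secondary_forest",
    4: "plantation_forest",
    5: "primary_vegetation",
    6: "low_input_agriculture",
    7: "agroforestry",
    8: "pasture",
    9: "built_up",
}
LU = {v: k for k, v in LANDUSE_LEGEND.items()}

COCOA_NONE, COCOA_FULL_SUN, COCOA_AGROFORESTRY = 0, 1, 2
COCOA_TYPE_LEGEND = {COCOA_NONE: "none", COCOA_FULL_SUN: "full_sun", COCOA_AGROFORESTRY: "agroforestry"}


@dataclass
class LandUseRaster:
    """Harmonized land use plus companion cocoa masks."""

    landuse: CategoricalRaster
    cocoa_mask: np.ndarray  # boolean
    cocoa_type: np.ndarray  # int8: 0 none, 1 full_sun, 2 agroforestry
    audit: list[dict] = field(default_factory=list)  # per-step hectares

    def __post_init__(self) -> None:
        shape = self.landuse.grid.shape
        if self.cocoa_mask.shape != shape or self.cocoa_type.shape != shape:
            raise GeodataError("cocoa masks must match the land-use grid")
        cocoa_lu = np.isin(self.landuse.codes, [LU["low_input_agriculture"], LU["agroforestry"]])
        if np.any(self.cocoa_mask & ~cocoa_lu):
            raise GeodataError("cocoa cells must carry low_input_agriculture or agroforestry")
        if np.any(self.cocoa_mask != (self.cocoa_type != COCOA_NONE)):
            raise GeodataError("cocoa_type must be set exactly on cocoa_mask cells")

    @property
    def grid(self) -> GridSpec:
        return self.landuse.grid

    def class_mask(self, *names: str) -> np.ndarray:
        return self.landuse.mask_of(*names)


def allocate_pasture(
    candidate_mask: np.ndarray,
    suitability: ContinuousRaster,
    area_budget_ha: float,
) -> np.ndarray:
    """Greedy pasture selection: take candidate cells in strictly decreasing
    suitability order (ties by row, then column) until the selected area
    reaches the budget or candidates run out."""
    if area_budget_ha < 0:
        raise GeodataError(f"pasture budget must be non-negative, got {area_budget_ha}")
    grid = suitability.grid
    if candidate_mask.shape != grid.shape:
        raise GeodataError("candidate mask does not match the suitability grid")
    if np.isnan(suitability.values[candidate_mask]).any():
        raise GeodataError("suitability undefined on some candidate cells")
    selected = np.zeros(grid.shape, dtype=bool)
    if area_budget_ha == 0 or not candidate_mask.any():
        return selected
    rows, cols = np.nonzero(candidate_mask)
    suit = suitability.values[rows, cols]
    # sort by (-suitability, row, col): lexsort uses the last key as primary
    order = np.lexsort((cols, rows, -suit))
    cell_area = grid.cell_area_ha
    k = int(np.ceil(area_budget_ha / cell_area))
    if k >= order.size:
        k = order.size
        logger.warning(
            "pasture budget %.1f ha exceeds candidate area %.1f ha; allocation saturates",
            area_budget_ha, order.size * cell_area,
        )
    chosen = order[:k]
    selected[rows[chosen], cols[chosen]] = True
    return selected


def classify_forest(
    forest_mask: np.ndarray,
    management: CategoricalRaster,
    integrity: ContinuousRaster,
    flii_threshold: float,
) -> dict[str, np.ndarray]:
    """Partition forest cells into the four forest classes.

    management=primary -> primary_forest; management=plantation ->
    plantation_forest; otherwise integrity >= threshold splits lightly-used
    from secondary forest.
    """
    if management.grid != integrity.grid:
        raise GeodataError("management and integrity layers are on different grids")
    primary = forest_mask & management.mask_of("primary")
    plantation = forest_mask & management.mask_of("plantation") & ~primary
    rest = forest_mask & ~primary & ~plantation
    with np.errstate(invalid="ignore"):
        high = integrity.values >= flii_threshold
    lightly = rest & high
    secondary = rest & ~high
    return {
        "primary_forest": primary,
        "plantation_forest": plantation,
        "lightly_used_natural_forest": lightly,
        "secondary_forest": secondary,
    }


def harmonize(bundle: LandscapeBundle, cfg: RunConfig) -> LandUseRaster:
    """Run the six-step priority allocation over a landscape bundle."""
    grid = bundle.grid
    if cfg.grid != grid:
        raise GeodataError("config grid differs from bundle grid")
    base = bundle.base_landcover
    nodata = base.nodata_code
    codes = np.full(grid.shape, nodata, dtype=np.int32)
    allocated = ~base.valid_mask | base.mask_of("water")  # water excluded from all budgets
    audit: list[dict] = []

    def record(step: str, mask: np.ndarray) -> None:
        audit.append({"step": step, "cells": int(mask.sum()), "area_ha": log_area(step, mask, grid)})

    # 1. cocoa (highest priority), typed by the shade hint
    cocoa = (bundle.cocoa_presence.codes == 1) & ~allocated
    agro_hint = bundle.cocoa_shade_hint.mask_of("agroforestry")
    cocoa_type = np.zeros(grid.shape, dtype=np.int8)
    cocoa_type[cocoa & agro_hint] = COCOA_AGROFORESTRY
    cocoa_type[cocoa & ~agro_hint] = COCOA_FULL_SUN
    codes[cocoa_type == COCOA_FULL_SUN] = LU["low_input_agriculture"]
    codes[cocoa_type == COCOA_AGROFORESTRY] = LU["agroforestry"]
    allocated |= cocoa
    record("cocoa", cocoa)

    # 2. remaining agriculture per hint
    agri = base.mask_of("agriculture") & ~allocated
    codes[agri & agro_hint] = LU["agroforestry"]
    codes[agri & ~agro_hint] = LU["low_input_agriculture"]
    allocated |= agri
    record("agriculture", agri)

    # 3. pasture
    candidates = base.mask_of("herbaceous", "shrub") & ~allocated
    pasture = allocate_pasture(candidates, bundle.livestock_density, cfg.pasture_area_budget_ha)
    codes[pasture] = LU["pasture"]
    allocated |= pasture
    record("pasture", pasture)
    # PNV pasture typing is audit-only, not a separate MSA class
    pnv_forest = pasture & bundle.pnv.mask_of("forest")
    audit.append(
        {
            "step": "pasture_on_forest_pnv",
            "cells": int(pnv_forest.sum()),
            "area_ha": float(pnv_forest.sum()) * grid.cell_area_ha,
        }
    )

    # 4. forest classes
    forest = base.mask_of("forest") & ~allocated
    for name, mask in classify_forest(
        forest, bundle.forest_management, bundle.forest_integrity, cfg.flii_threshold
    ).items():
        codes[mask] = LU[name]
        record(name, mask)
    allocated |= forest

    # 5. remaining vegetated cells -> primary vegetation
    veg = base.mask_of("forest", "herbaceous", "shrub", "agriculture") & ~allocated
    codes[veg] = LU["primary_vegetation"]
    allocated |= veg
    record("primary_vegetation", veg)

    # 6. bare + infrastructure -> built-up
    built = base.mask_of("bare", "infrastructure") & ~allocated
    codes[built] = LU["built_up"]
    allocated |= built
    record("built_up", built)

    unassigned = base.valid_mask & ~base.mask_of("water") & (codes == nodata)
    if unassigned.any():
        raise GeodataError(f"{int(unassigned.sum())} valid cells left unallocated")

    lu = CategoricalRaster(grid=grid, codes=codes, legend=dict(LANDUSE_LEGEND), nodata_code=nodata)
    return LandUseRaster(landuse=lu, cocoa_mask=cocoa, cocoa_type=cocoa_type, audit=audit)
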