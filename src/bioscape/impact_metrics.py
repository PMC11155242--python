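"""Yield downscaling, biodiversity impact metrics (BIM) and factors (BF).

Yields are disaggregated over cocoa cells proportionally to suitability so
that total production is conserved exactly.  BIM_total uses intactness loss
against the fully intact reference (1 − MSA); BIM_cocoa uses the cocoa
counterfactual loss restricted to cocoa cells.  BF divides BIM_cocoa by the
cell's production (per-tonne impact, ha·year·t⁻¹).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from bioscape.geodata_io import (
    CategoricalRaster,
    ContinuousRaster,
    GeodataError,
    GridSpec,
)
from bioscape.landuse_harmonizer import COCOA_AGROFORESTRY, COCOA_FULL_SUN, LandUseRaster

logger = logging.getLogger("bioscape.impact_metrics")


def downscale_yield(
    suitability: ContinuousRaster,
    cocoa_mask: np.ndarray,
    total_production_t: float,
    years: float = 1.0,
) -> ContinuousRaster:
    """Per-cell yield Y_i = S_i · P / (Σ_j S_j · A_j · years) on cocoa cells.

    Conserves Σ Y_i · A_i · years = total production exactly.
    """
    grid = suitability.grid
    if cocoa_mask.shape != grid.shape:
        raise GeodataError("cocoa mask off-grid")
    if not cocoa_mask.any():
        raise GeodataError("empty cocoa mask: nothing to downscale yields onto")
    if not total_production_t > 0:
        raise GeodataError("total production must be positive")
    if not years > 0:
        raise GeodataError("occupation years must be positive")
    s = suitability.values
    if np.any(~(s[cocoa_mask] > 0)):
        raise GeodataError("suitability must be positive (and defined) on every cocoa cell")
    denom = float(np.sum(s[cocoa_mask]) * grid.cell_area_ha * years)
    values = np.zeros(grid.shape)
    values[cocoa_mask] = s[cocoa_mask] * total_production_t / denom
    return ContinuousRaster(grid=grid, values=values)


def bim_total(
    msa_total: ContinuousRaster, ri: ContinuousRaster, grid: GridSpec
) -> tuple[ContinuousRaster, float]:
    """Cellwise (1 − MSA_i) · RI_i · A_i and its sum over valid cells."""
    if msa_total.grid != grid or ri.grid != grid:
        raise GeodataError("bim_total inputs on mismatched grids")
    cells = (1.0 - msa_total.values) * ri.values * grid.cell_area_ha
    raster = ContinuousRaster(grid=grid, values=cells)
    return raster, float(np.nansum(cells))


def bim_cocoa(
    msa_loss: ContinuousRaster,
    ri: ContinuousRaster,
    cocoa_mask: np.ndarray,
    grid: GridSpec,
) -> tuple[ContinuousRaster, float]:
    """Cellwise (MSA_nv,i − MSA_i) · RI_i · A_i on cocoa cells, 0 elsewhere."""
    if msa_loss.grid != grid or ri.grid != grid:
        raise GeodataError("bim_cocoa inputs on mismatched grids")
    if cocoa_mask.shape != grid.shape:
        raise GeodataError("cocoa mask off-grid")
    cells = np.where(cocoa_mask, msa_loss.values * ri.values * grid.cell_area_ha, 0.0)
    cells[np.isnan(msa_loss.values) | np.isnan(ri.values)] = np.nan
    raster = ContinuousRaster(grid=grid, values=cells)
    return raster, float(np.nansum(cells))


def bf_cocoa(
    bim_cocoa_raster: ContinuousRaster,
    yield_raster: ContinuousRaster,
    years: float = 1.0,
) -> ContinuousRaster:
    """Per-cocoa-cell BF_i = BIM_cocoa,i / (Y_i · A_i · years), ha·year·t⁻¹."""
    grid = bim_cocoa_raster.grid
    if yield_raster.grid != grid:
        raise GeodataError("bf inputs on mismatched grids")
    y = yield_raster.values
    cocoa = y > 0
    if np.any(cocoa & np.isnan(bim_cocoa_raster.values)):
        raise GeodataError("bim_cocoa undefined on a producing cell")
    values = np.full(grid.shape, np.nan)
    values[cocoa] = bim_cocoa_raster.values[cocoa] / (y[cocoa] * grid.cell_area_ha * years)
    return ContinuousRaster(grid=grid, values=values)


def department_aggregate(
    departments: CategoricalRaster,
    landuse: LandUseRaster,
    bf_raster: ContinuousRaster,
    bim_cocoa_raster: ContinuousRaster,
    bim_total_raster: ContinuousRaster,
    yield_raster: ContinuousRaster,
    years: float = 1.0,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-department production, BF (all / full-sun / agroforestry), BIM sums
    and the relative share bim_cocoa / bim_total.

    ``weighted=False`` averages cell BF unweighted over the department's cocoa
    cells (the default reading); ``weighted=True`` weights by per-cell
    production, which makes tonnes × BF attribution exactly mass-consistent.
    Departments without cocoa get NaN in the bf columns (absent, not zero).
    """
    grid = departments.grid
    for layer in (bf_raster, bim_cocoa_raster, bim_total_raster, yield_raster):
        if layer.grid != grid:
            raise GeodataError("department aggregation inputs on mismatched grids")
    if landuse.grid != grid:
        raise GeodataError("land use on a different grid")
    cell_area = grid.cell_area_ha
    production_cells = yield_raster.values * cell_area * years
    cocoa = landuse.cocoa_mask
    rows = []
    dept_ids = sorted(int(c) for c in np.unique(departments.codes) if c != departments.nodata_code)
    for dept in dept_ids:
        in_dept = departments.codes == dept
        dept_cocoa = in_dept & cocoa
        row: dict = {
            "department_id": dept,
            "department": departments.legend.get(dept, str(dept)),
            "production_t": float(np.nansum(production_cells[dept_cocoa])),
            "bim_cocoa": float(np.nansum(bim_cocoa_raster.values[in_dept])),
            "bim_total": float(np.nansum(bim_total_raster.values[in_dept])),
        }
        for col, mask in (
            ("bf_all", dept_cocoa),
            ("bf_fullsun", dept_cocoa & (landuse.cocoa_type == COCOA_FULL_SUN)),
            ("bf_agro", dept_cocoa & (landuse.cocoa_type == COCOA_AGROFORESTRY)),
        ):
            row[col] = _bf_average(bf_raster.values, production_cells, mask, weighted)
        row["share"] = row["bim_cocoa"] / row["bim_total"] if row["bim_total"] > 0 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("department_id")
    n_clamped = int(np.sum(cocoa & (bim_cocoa_raster.values == 0)))
    if n_clamped:
        logger.info("department_aggregate: %d cocoa cells contribute zero BIM (clamped losses)", n_clamped)
    return table


def _bf_average(bf: np.ndarray, production: np.ndarray, mask: np.ndarray, weighted: bool) -> float:
    mask = mask & ~np.isnan(bf)
    if not mask.any():
        return float("nan")
    if weighted:
        w = production[mask]
        return float(np.sum(bf[mask] * w) / np.sum(w))
    return float(bf[mask].mean())
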