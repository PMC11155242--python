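"""Rarity-weighted richness from species ranges and its rarity-index transform.

Per species, each cell receives (range area within the cell) / (global range
area), zeroed where the cell's elevation falls outside the species' envelope.
Aggregated RWR is the cellwise sum over species.  The rarity index (RI)
log-transforms the aggregate, normalizes to mean 1, and floors the result.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from bioscape.geodata_io import (
    ContinuousRaster,
    GeodataError,
    GridSpec,
    read_geojson,
)
from bioscape.synthetic_landscape import SyntheticSpecies

logger = logging.getLogger("bioscape.biodiversity_importance")


def _elevation_ok(dem: ContinuousRaster, lo: float, hi: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (dem.values >= lo) & (dem.values <= hi)


def species_rwr(
    species: SyntheticSpecies,
    dem: ContinuousRaster,
    grid: GridSpec,
    geometry: BaseGeometry | None = None,
) -> ContinuousRaster:
    """One species' RWR raster.

    With ``geometry`` given, the in-cell range area is the exact
    polygon-cell intersection area; otherwise the species' cell mask is
    taken at full cell area.  Cells whose DEM value lies outside the
    elevation envelope contribute zero.
    """
    if dem.grid != grid:
        raise GeodataError("dem grid differs from target grid")
    if not species.global_range_area_ha > 0:
        raise GeodataError(f"{species.species_id}: zero global range area")
    if geometry is not None:
        area_ha = _cell_intersection_areas(geometry, grid)
    else:
        if species.range_mask.shape != grid.shape:
            raise GeodataError(f"{species.species_id}: range mask off-grid")
        area_ha = species.range_mask.astype(float) * grid.cell_area_ha
    suitable = _elevation_ok(dem, species.elevation_min, species.elevation_max)
    values = np.where(suitable, area_ha, 0.0) / species.global_range_area_ha
    return ContinuousRaster(grid=grid, values=values)


def _cell_intersection_areas(geometry: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Exact per-cell intersection area (ha) of a polygon with the grid."""
    out = np.zeros(grid.shape)
    minx, miny, maxx, maxy = geometry.bounds
    _, c0, _ = grid.index_of(np.array([minx]), np.array([grid.origin_y]))
    r0, _, _ = grid.index_of(np.array([grid.origin_x]), np.array([maxy]))
    c_lo = max(0, int(c0[0]))
    r_lo = max(0, int(r0[0]))
    c_hi = min(grid.n_cols, int(np.ceil((maxx - grid.origin_x) / grid.cell_size)))
    r_hi = min(grid.n_rows, int(np.ceil((grid.origin_y - miny) / grid.cell_size)))
    prepped = shapely.prepared.prep(geometry)
    for r in range(r_lo, r_hi):
        y1 = grid.origin_y - r * grid.cell_size
        y0 = y1 - grid.cell_size
        for c in range(c_lo, c_hi):
            x0 = grid.origin_x + c * grid.cell_size
            cell = box(x0, y0, x0 + grid.cell_size, y1)
            if not prepped.intersects(cell):
                continue
            out[r, c] = geometry.intersection(cell).area / 10_000.0
    return out


def aggregate_rwr(per_species: Sequence[ContinuousRaster]) -> ContinuousRaster:
    """Cellwise sum of per-species RWR rasters (shared grid enforced)."""
    if not per_species:
        raise GeodataError("need at least one species raster")
    grid = per_species[0].grid
    total = np.zeros(grid.shape)
    for r in per_species:
        if r.grid != grid:
            raise GeodataError("species rasters live on different grids")
        total = total + np.where(np.isnan(r.values), 0.0, r.values)
    # propagate cells that are nodata in every input
    all_nan = np.ones(grid.shape, dtype=bool)
    for r in per_species:
        all_nan &= np.isnan(r.values)
    total[all_nan] = np.nan
    return ContinuousRaster(grid=grid, values=total)


def rwr_to_ri(
    rwr: ContinuousRaster,
    ri_floor: float = 0.05,
    transform: str = "log1p_scaled",
) -> ContinuousRaster:
    """Transform aggregated RWR to the rarity index.

    Default transform t = ln(1 + rwr / mean(positive rwr)) is unit-free and
    defined at zero; ``transform="log"`` is the raw-ln alternative (only
    positive cells carry scores, zero cells fall straight to the floor).
    Scores are divided by their mean over valid cells — an average cell gets
    exactly 1 — then floored at ``ri_floor``.
    """
    if not ri_floor > 0:
        raise GeodataError("ri_floor must be positive")
    valid = rwr.valid_mask
    vals = rwr.values
    if valid.any() and np.nanmin(vals) < 0:
        raise GeodataError("aggregated RWR must be non-negative")
    out = np.full(rwr.grid.shape, np.nan)
    positive = valid & (vals > 0)
    if not positive.any():
        warnings.warn("all-zero RWR layer: RI set to the floor everywhere", stacklevel=2)
        out[valid] = ri_floor
        return ContinuousRaster(grid=rwr.grid, values=out)
    if transform == "log1p_scaled":
        r_bar = float(vals[positive].mean())
        t = np.log1p(np.where(valid, vals, 0.0) / r_bar)
        score_mask = valid
    elif transform == "log":
        t = np.full(rwr.grid.shape, np.nan)
        t[positive] = np.log(vals[positive])
        score_mask = positive
    else:
        raise GeodataError(f"unknown transform {transform!r}")
    t_mean = float(t[score_mask].mean())
    if t_mean == 0:
        s = np.ones(rwr.grid.shape)
    else:
        s = t / t_mean
    out[valid] = ri_floor
    out[score_mask] = np.maximum(s[score_mask], ri_floor)
    return ContinuousRaster(grid=rwr.grid, values=out)


def load_species_features(path) -> list[tuple[SyntheticSpecies, BaseGeometry]]:
    """Read species ranges from GeoJSON (id, elevation_min/max, global_range_area)."""
    out = []
    for geom, props in read_geojson(path):
        sp = SyntheticSpecies(
            species_id=str(props["id"]),
            range_mask=np.zeros((1, 1), dtype=bool),  # geometry path: mask unused
            elevation_min=float(props["elevation_min"]),
            elevation_max=float(props["elevation_max"]),
            global_range_area_ha=float(props["global_range_area"]),
        )
        out.append((sp, geom))
    return out
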