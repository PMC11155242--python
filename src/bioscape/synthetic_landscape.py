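"""Synthetic inputs: landscape rasters, species ranges, roads, departments, trade.

Everything is seeded and deterministic.  Spatial structure comes from
Gaussian-smoothed noise fields assigned to classes by rank (quantile bins),
which gives autocorrelated patches with exactly-controlled class proportions.
Species ranges are connected blobs grown cell by cell; range sizes follow a
log-normal, so the aggregated rarity-weighted richness is right-skewed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from bioscape.geodata_io import (
    CategoricalRaster,
    ContinuousRaster,
    GeodataError,
    GridSpec,
)

logger = logging.getLogger("bioscape.synthetic_landscape")

BASE_LEGEND = {
    1: "forest",
    2: "herbaceous",
    3: "shrub",
    4: "agriculture",
    5: "bare",
    6: "infrastructure",
    7: "water",
}
BASE_CODE = {v: k for k, v in BASE_LEGEND.items()}

SHADE_LEGEND = {1: "full_sun", 2: "agroforestry"}
MGMT_LEGEND = {1: "primary", 2: "plantation", 3: "other"}
PNV_LEGEND = {1: "forest", 2: "grassland"}
BINARY_LEGEND = {0: "absent", 1: "present"}

DEFAULT_CLASS_MIX = {
    "forest": 0.35,
    "herbaceous": 0.14,
    "shrub": 0.10,
    "agriculture": 0.30,
    "bare": 0.04,
    "infrastructure": 0.02,
    "water": 0.05,
}

UNKNOWN = "UNKNOWN"
DOMESTIC = "DOMESTIC"


@dataclass
class LandscapeBundle:
    """All rasters + vectors one pipeline run consumes, on one shared grid."""

    grid: GridSpec
    base_landcover: CategoricalRaster
    cocoa_presence: CategoricalRaster
    cocoa_shade_hint: CategoricalRaster  # defined on agriculture ∪ cocoa cells
    forest_management: CategoricalRaster
    forest_integrity: ContinuousRaster
    livestock_density: ContinuousRaster
    pnv: CategoricalRaster
    suitability: ContinuousRaster
    dem: ContinuousRaster
    roads: list[LineString] = field(default_factory=list)
    departments: list[tuple[int, str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "base_landcover",
            "cocoa_presence",
            "cocoa_shade_hint",
            "forest_management",
            "forest_integrity",
            "livestock_density",
            "pnv",
            "suitability",
            "dem",
        ):
            layer = getattr(self, name)
            if layer.grid != self.grid:
                raise GeodataError(f"bundle layer {name} is not on the shared grid")
        cocoa = self.cocoa_presence.codes == 1
        eligible = self.base_landcover.mask_of("agriculture", "forest")
        if np.any(cocoa & ~eligible):
            raise GeodataError("cocoa_presence=1 outside agriculture/forest cells")
        if np.any(cocoa & ~(self.suitability.values > 0)):
            raise GeodataError("suitability must be positive on every cocoa cell")


@dataclass
class SyntheticSpecies:
    """A species range as a cell mask plus elevation envelope and global area."""

    species_id: str
    range_mask: np.ndarray  # boolean, grid shape
    elevation_min: float
    elevation_max: float
    global_range_area_ha: float

    def __post_init__(self) -> None:
        if not self.elevation_min < self.elevation_max:
            raise GeodataError(f"{self.species_id}: elevation_min must be < elevation_max")
        if not self.global_range_area_ha > 0:
            raise GeodataError(f"{self.species_id}: global range area must be positive")


@dataclass(frozen=True)
class SyntheticTradeSpec:
    n_exporters: int = 8
    n_importers: int = 10
    untraced_fraction: float = 0.544
    export_fraction: float = 0.93

    def __post_init__(self) -> None:
        for name in ("untraced_fraction", "export_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeodataError(f"{name} must be in [0,1], got {v}")
        if self.n_exporters < 1 or self.n_importers < 1:
            raise GeodataError("need at least one exporter and one importer")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-smoothed standard-normal noise, re-standardized."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _rank_assign(field_vals: np.ndarray, proportions: Sequence[tuple[int, float]]) -> np.ndarray:
    """Assign codes to cells by the rank of a continuous field.

    The lowest ``p_0`` fraction of cells gets the first code, the next
    fraction the second, etc.  Realized proportions are exact up to integer
    rounding of cell counts.
    """
    flat = field_vals.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    out = np.empty(n, dtype=np.int32)
    start = 0
    cum = 0.0
    for i, (code, p) in enumerate(proportions):
        cum += p
        stop = n if i == len(proportions) - 1 else int(round(cum * n))
        out[order[start:stop]] = code
        start = stop
    return out.reshape(field_vals.shape)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


def generate_landscape(
    seed: int | np.random.SeedSequence,
    grid: GridSpec,
    class_mix: Mapping[str, float] | None = None,
    cocoa_fraction: float = 0.15,
    agroforestry_share: float = 0.4,
    n_roads: int = 5,
    n_departments: int = 8,
    sigma: float = 3.0,
) -> LandscapeBundle:
    """Generate a full input bundle.

    ``class_mix`` maps base class name -> target proportion (must sum to 1).
    ``cocoa_fraction`` is the fraction of agriculture+forest cells that carry
    cocoa; ``agroforestry_share`` the hint share of agroforestry among
    agriculture/cocoa cells.
    """
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    unknown = set(mix) - set(BASE_CODE)
    if unknown:
        raise GeodataError(f"unknown base classes in class_mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise GeodataError(f"class_mix proportions must sum to 1, got {total}")
    if not 0.0 <= cocoa_fraction <= 1.0:
        raise GeodataError("cocoa_fraction must be in [0,1]")
    if cocoa_fraction > 0 and mix.get("agriculture", 0.0) + mix.get("forest", 0.0) <= 0:
        raise GeodataError("cocoa requires a positive agriculture+forest proportion")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    keys = ("base", "cocoa", "shade", "mgmt", "integrity", "livestock", "pnv", "suit", "dem", "roads", "depts")
    rngs = {k: np.random.Generator(np.random.PCG64(child)) for k, child in zip(keys, ss.spawn(len(keys)))}

    # base land cover: rank-assigned smoothed field, ordered so ecologically
    # adjacent classes touch (water lowest, infrastructure highest).
    order = ["water", "forest", "shrub", "herbaceous", "agriculture", "bare", "infrastructure"]
    props = [(BASE_CODE[name], mix.get(name, 0.0)) for name in order]
    base_field = _smooth_field(rngs["base"], grid.shape, sigma)
    base_codes = _rank_assign(base_field, props)
    base = CategoricalRaster(grid=grid, codes=base_codes, legend=dict(BASE_LEGEND))

    # cocoa presence among agriculture+forest cells (highest cocoa-field values)
    eligible = base.mask_of("agriculture", "forest")
    cocoa_field = _smooth_field(rngs["cocoa"], grid.shape, sigma)
    cocoa = np.zeros(grid.shape, dtype=np.int32)
    n_cocoa = int(round(cocoa_fraction * int(eligible.sum())))
    if n_cocoa > 0:
        vals = np.where(eligible, cocoa_field, -np.inf).ravel()
        top = np.argpartition(vals, -n_cocoa)[-n_cocoa:]
        cocoa.ravel()[top] = 1
    cocoa_r = CategoricalRaster(grid=grid, codes=cocoa, legend=dict(BINARY_LEGEND))

    # shade hint on agriculture ∪ cocoa cells
    hint_domain = base.mask_of("agriculture") | (cocoa == 1)
    shade_field = _smooth_field(rngs["shade"], grid.shape, sigma)
    thr = np.quantile(shade_field[hint_domain], 1.0 - agroforestry_share) if hint_domain.any() else np.inf
    shade = np.full(grid.shape, -9999, dtype=np.int32)
    shade[hint_domain] = np.where(shade_field[hint_domain] >= thr, 2, 1)
    shade_r = CategoricalRaster(grid=grid, codes=shade, legend=dict(SHADE_LEGEND))

    # forest management: mostly other, patches of primary and plantation
    mgmt_field = _smooth_field(rngs["mgmt"], grid.shape, sigma)
    mgmt = _rank_assign(mgmt_field, [(2, 0.15), (3, 0.55), (1, 0.30)])
    mgmt_r = CategoricalRaster(grid=grid, codes=mgmt, legend=dict(MGMT_LEGEND))

    # forest integrity 0-10: interior distance within forest patches + noise
    forest = base.mask_of("forest")
    interior = ndimage.distance_transform_edt(forest)
    if interior.max() > 0:
        interior = interior / interior.max()
    integ = np.clip(
        10.0 * (0.75 * interior + 0.25 * (0.5 + 0.5 * _smooth_field(rngs["integrity"], grid.shape, sigma))),
        0.0,
        10.0,
    )
    integ_r = ContinuousRaster(grid=grid, values=integ)

    livestock = np.exp(0.8 * _smooth_field(rngs["livestock"], grid.shape, sigma))
    livestock_r = ContinuousRaster(grid=grid, values=livestock)

    pnv = _rank_assign(_smooth_field(rngs["pnv"], grid.shape, sigma), [(2, 0.35), (1, 0.65)])
    pnv_r = CategoricalRaster(grid=grid, codes=pnv, legend=dict(PNV_LEGEND))

    suit = 0.05 + np.exp(0.6 * _smooth_field(rngs["suit"], grid.shape, sigma))
    suit_r = ContinuousRaster(grid=grid, values=suit)

    dem_vals = 200.0 + 400.0 * (0.5 + 0.5 * _smooth_field(rngs["dem"], grid.shape, sigma * 2))
    dem_r = ContinuousRaster(grid=grid, values=dem_vals)

    roads = _generate_roads(rngs["roads"], grid, n_roads)
    departments = generate_departments(rngs["depts"], grid, n_departments)

    bundle = LandscapeBundle(
        grid=grid,
        base_landcover=base,
        cocoa_presence=cocoa_r,
        cocoa_shade_hint=shade_r,
        forest_management=mgmt_r,
        forest_integrity=integ_r,
        livestock_density=livestock_r,
        pnv=pnv_r,
        suitability=suit_r,
        dem=dem_r,
        roads=roads,
        departments=departments,
    )
    logger.info(
        "generated landscape %dx%d: %d cocoa cells, %d roads, %d departments",
        grid.n_rows, grid.n_cols, int(cocoa.sum()), len(roads), len(departments),
    )
    return bundle


def _generate_roads(rng: np.random.Generator, grid: GridSpec, n_roads: int) -> list[LineString]:
    """Random polylines crossing the domain (3 bends each)."""
    x0, x1 = grid.origin_x, grid.origin_x + grid.n_cols * grid.cell_size
    y1, y0 = grid.origin_y, grid.origin_y - grid.n_rows * grid.cell_size
    roads = []
    for _ in range(n_roads):
        if rng.random() < 0.5:  # west-east
            xs = np.linspace(x0, x1, 4)
            ys = rng.uniform(y0, y1, size=4)
        else:  # north-south
            ys = np.linspace(y0, y1, 4)
            xs = rng.uniform(x0, x1, size=4)
        roads.append(LineString(np.column_stack([xs, ys])))
    return roads


def generate_departments(
    rng: np.random.Generator, grid: GridSpec, n_departments: int
) -> list[tuple[int, str, object]]:
    """Partition the domain into rectangles by recursive seeded splits (BSP)."""
    if n_departments < 1:
        raise GeodataError("need at least one department")
    x0, x1 = grid.origin_x, grid.origin_x + grid.n_cols * grid.cell_size
    y1, y0 = grid.origin_y, grid.origin_y - grid.n_rows * grid.cell_size
    rects = [(x0, y0, x1, y1)]
    while len(rects) < n_departments:
        # split the largest rectangle
        i = max(range(len(rects)), key=lambda k: (rects[k][2] - rects[k][0]) * (rects[k][3] - rects[k][1]))
        ax0, ay0, ax1, ay1 = rects.pop(i)
        frac = rng.uniform(0.35, 0.65)
        if (ax1 - ax0) >= (ay1 - ay0):
            xm = ax0 + frac * (ax1 - ax0)
            rects += [(ax0, ay0, xm, ay1), (xm, ay0, ax1, ay1)]
        else:
            ym = ay0 + frac * (ay1 - ay0)
            rects += [(ax0, ay0, ax1, ym), (ax0, ym, ax1, ay1)]
    return [
        (i + 1, f"dept_{i + 1:02d}", box(*rect))
        for i, rect in enumerate(sorted(rects))
    ]


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------


def generate_species(
    seed: int | np.random.SeedSequence,
    n_species: int,
    grid: GridSpec,
    dem: ContinuousRaster,
    median_range_cells: float = 60.0,
    range_sigma: float = 1.0,
    elevation_mismatch_rate: float = 0.1,
    global_area_inflation: float = 1.0,
) -> list[SyntheticSpecies]:
    """Grow ``n_species`` connected range blobs with log-normal sizes.

    Most species get an elevation envelope covering their range's DEM values;
    a fraction ``elevation_mismatch_rate`` gets a truncated envelope so the
    elevation filter bites.  ``global_area_inflation`` > 1 emulates ranges
    extending beyond the domain.
    """
    if n_species < 1:
        raise GeodataError("n_species must be at least 1")
    if dem.grid != grid:
        raise GeodataError("dem must live on the target grid")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    n_cells = grid.n_rows * grid.n_cols
    sizes = np.minimum(
        np.maximum(1, np.round(median_range_cells * np.exp(range_sigma * rng.standard_normal(n_species)))),
        n_cells,
    ).astype(int)
    species = []
    for k in range(n_species):
        mask = _grow_blob(rng, grid.shape, int(sizes[k]))
        dem_vals = dem.values[mask]
        dem_vals = dem_vals[~np.isnan(dem_vals)]
        lo, hi = (float(dem_vals.min()), float(dem_vals.max())) if dem_vals.size else (0.0, 1.0)
        if rng.random() < elevation_mismatch_rate and dem_vals.size > 1 and hi > lo:
            hi = float(np.quantile(dem_vals, 0.6))  # truncate: some cells filtered out
            if hi <= lo:
                hi = lo + 1e-6
        else:
            lo, hi = lo - 1.0, hi + 1.0
        area = float(mask.sum()) * grid.cell_area_ha * global_area_inflation
        species.append(
            SyntheticSpecies(
                species_id=f"sp_{k:04d}",
                range_mask=mask,
                elevation_min=lo,
                elevation_max=hi,
                global_range_area_ha=area,
            )
        )
    return species


def _grow_blob(rng: np.random.Generator, shape: tuple[int, int], size: int) -> np.ndarray:
    """Random region growing from a seed cell — connected by construction."""
    n_rows, n_cols = shape
    r0 = int(rng.integers(n_rows))
    c0 = int(rng.integers(n_cols))
    mask = np.zeros(shape, dtype=bool)
    mask[r0, c0] = True
    frontier = []
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rr, cc = r0 + dr, c0 + dc
        if 0 <= rr < n_rows and 0 <= cc < n_cols:
            frontier.append((rr, cc))
    while mask.sum() < size and frontier:
        i = int(rng.integers(len(frontier)))
        r, c = frontier.pop(i)
        if mask[r, c]:
            continue
        mask[r, c] = True
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and not mask[rr, cc]:
                frontier.append((rr, cc))
    return mask


def species_to_features(species: Sequence[SyntheticSpecies], grid: GridSpec):
    """Dissolve each species' cell mask into a (Multi)Polygon feature."""
    feats = []
    for sp in species:
        rows, cols = np.nonzero(sp.range_mask)
        boxes = [
            box(
                grid.origin_x + c * grid.cell_size,
                grid.origin_y - (r + 1) * grid.cell_size,
                grid.origin_x + (c + 1) * grid.cell_size,
                grid.origin_y - r * grid.cell_size,
            )
            for r, c in zip(rows.tolist(), cols.tolist())
        ]
        feats.append(
            (
                unary_union(boxes),
                {
                    "id": sp.species_id,
                    "elevation_min": sp.elevation_min,
                    "elevation_max": sp.elevation_max,
                    "global_range_area": sp.global_range_area_ha,
                },
            )
        )
    return feats


# ---------------------------------------------------------------------------
# trade
# ---------------------------------------------------------------------------


def generate_trade(
    seed: int | np.random.SeedSequence,
    dept_production: Mapping[int, float],
    spec: SyntheticTradeSpec,
) -> pd.DataFrame:
    """Build a flow table (department_id, exporter, importer, volume_t).

    Mass balance is exact: exported tonnes = export_fraction × total
    production, the untraced_fraction of exports carries department UNKNOWN,
    and the non-exported remainder appears as traced DOMESTIC rows.  Each
    department's traced volume never exceeds its production.
    """
    if any(v < 0 for v in dept_production.values()):
        raise GeodataError("department productions must be non-negative")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    total = float(sum(dept_production.values()))
    if total <= 0:
        raise GeodataError("total production must be positive")
    exporters = [f"exporter_{i:02d}" for i in range(1, spec.n_exporters + 1)]
    importers = [f"importer_{i:02d}" for i in range(1, spec.n_importers + 1)]

    exported = spec.export_fraction * total
    untraced = spec.untraced_fraction * exported
    traced_exp_share = (exported - untraced) / total
    domestic_share = 1.0 - spec.export_fraction

    rows: list[tuple[object, str, str, float]] = []
    for dept in sorted(dept_production):
        prod = float(dept_production[dept])
        if prod <= 0:
            continue
        vol = prod * traced_exp_share
        if vol > 0:
            rows.extend(_split_volume(rng, dept, vol, exporters, importers))
        dom = prod * domestic_share
        if dom > 0:
            exp = exporters[int(rng.integers(len(exporters)))]
            rows.append((dept, exp, DOMESTIC, dom))
    if untraced > 0:
        rows.extend(_split_volume(rng, UNKNOWN, untraced, exporters, importers))
    df = pd.DataFrame(rows, columns=["department_id", "exporter", "importer", "volume_t"])
    logger.info(
        "trade table: %d rows, %.1f t total (%.1f t exported, %.1f t untraced)",
        len(df), df.volume_t.sum(), exported, untraced,
    )
    return df


def _split_volume(
    rng: np.random.Generator,
    dept: object,
    volume: float,
    exporters: Sequence[str],
    importers: Sequence[str],
) -> list[tuple[object, str, str, float]]:
    """Dirichlet split of a volume over a random subset of exporter×importer pairs."""
    n_pairs = int(rng.integers(1, min(4, len(exporters) * len(importers)) + 1))
    pairs = set()
    while len(pairs) < n_pairs:
        pairs.add(
            (
                exporters[int(rng.integers(len(exporters)))],
                importers[int(rng.integers(len(importers)))],
            )
        )
    shares = rng.dirichlet(np.ones(len(pairs)))
    return [
        (dept, exp, imp, volume * float(s))
        for (exp, imp), s in zip(sorted(pairs), shares)
    ]
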