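"""Shared grid model, raster/vector/tabular I/O and run configuration.

Rasters are single-band ESRI ASCII grids (``.asc``) with a JSON sidecar
(``<path>.aux.json``) carrying the CRS identifier, the raster kind
(categorical or continuous) and, for categorical layers, the legend.
Vectors are GeoJSON; tables are UTF-8 CSV with a header and "." decimal.

Every layer in one pipeline run lives on a single :class:`GridSpec`;
operations that combine layers refuse mixed grids rather than resampling
implicitly.  Grid convention: top-left origin, row-major, 0-based indices,
half-open cell intervals (a point on the shared edge of two cells belongs
to the cell with the larger index along that axis).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import shapely
import yaml
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("bioscape.geodata_io")

#: nodata code used for categorical rasters unless a file says otherwise.
DEFAULT_NODATA_CODE = -9999
#: nodata written to ASCII grids for continuous rasters (NaN in memory).
CONTINUOUS_NODATA = -9999.0


class GeodataError(ValueError):
    """Raised on malformed files, mixed grids, or contract violations."""


# ---------------------------------------------------------------------------
# Grid model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Georeferenced regular grid; ``origin_x/origin_y`` is the top-left corner.

    ``cell_size`` is in metres; rows increase downwards (decreasing y).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_id: str = "local-metre"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeodataError(f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}")
        if not self.cell_size > 0:
            raise GeodataError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares, derived from cell_size (never stored)."""
        return self.cell_size**2 / 10_000.0

    @property
    def total_area_ha(self) -> float:
        return self.n_rows * self.n_cols * self.cell_area_ha

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate arrays of shape (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.broadcast_to(xs, self.shape).copy(), np.broadcast_to(ys[:, None], self.shape).copy()

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point plus an in-bounds mask.

        Half-open convention: a point exactly on an interior edge belongs to
        the cell on its right / below.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return row, col, ok


def _require_same_grid(a: GridSpec, b: GridSpec, what: str = "layers") -> None:
    if a != b:
        raise GeodataError(f"{what} live on different grids: {a} vs {b}")


# ---------------------------------------------------------------------------
# Raster types
# ---------------------------------------------------------------------------


@dataclass
class CategoricalRaster:
    """Integer-coded raster with a legend mapping code -> class name."""

    grid: GridSpec
    codes: np.ndarray
    legend: Mapping[int, str]
    nodata_code: int = DEFAULT_NODATA_CODE

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise GeodataError("categorical raster codes must be integers")
        self.codes = self.codes.astype(np.int32)
        if self.codes.shape != self.grid.shape:
            raise GeodataError(
                f"codes shape {self.codes.shape} does not match grid {self.grid.shape}"
            )
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.codes).tolist()) - {self.nodata_code}
        missing = present - set(self.legend)
        if missing:
            raise GeodataError(f"codes {sorted(missing)} missing from legend")
        if any(c < 0 for c in present):
            raise GeodataError("valid categorical codes must be non-negative")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata_code

    def mask_of(self, *class_names: str) -> np.ndarray:
        wanted = {code for code, name in self.legend.items() if name in class_names}
        return np.isin(self.codes, sorted(wanted))

    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class ContinuousRaster:
    """Float raster; nodata is NaN in memory."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GeodataError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if np.isinf(self.values).any():
            raise GeodataError("continuous raster contains non-finite (inf) values")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


Raster = CategoricalRaster | ContinuousRaster


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid + JSON sidecar)
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid plus JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid = raster.grid
    if isinstance(raster, CategoricalRaster):
        nodata: float = raster.nodata_code
        data = raster.codes
        meta = {
            "kind": "categorical",
            "crs_id": grid.crs_id,
            "nodata_code": int(raster.nodata_code),
            "legend": {str(k): v for k, v in sorted(raster.legend.items())},
        }
        fmt = "%d"
    else:
        nodata = CONTINUOUS_NODATA
        data = np.where(np.isnan(raster.values), CONTINUOUS_NODATA, raster.values)
        meta = {"kind": "continuous", "crs_id": grid.crs_id, "nodata": CONTINUOUS_NODATA}
        fmt = "%.12g"
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata:g}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8")
    return path


def read_raster(path: str | Path, expected_kind: str) -> Raster:
    """Read an ASCII-grid raster; ``expected_kind`` is 'categorical' or 'continuous'.

    Fails loudly on missing files, missing sidecars (unreadable CRS), or a
    kind mismatch — never silently defaults.
    """
    path = Path(path)
    if expected_kind not in ("categorical", "continuous"):
        raise GeodataError(f"expected_kind must be categorical|continuous, got {expected_kind!r}")
    if not path.exists():
        raise GeodataError(f"raster file does not exist: {path}")
    side = _sidecar_path(path)
    if not side.exists():
        raise GeodataError(f"sidecar missing (CRS unreadable): {side}")
    meta = json.loads(side.read_text(encoding="utf-8"))
    if "crs_id" not in meta:
        raise GeodataError(f"sidecar {side} carries no CRS identifier")
    if meta.get("kind") != expected_kind:
        raise GeodataError(f"{path} is kind={meta.get('kind')!r}, expected {expected_kind!r}")

    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (n_rows, n_cols):
        raise GeodataError(f"{path}: body shape {body.shape} contradicts header {(n_rows, n_cols)}")
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        crs_id=str(meta["crs_id"]),
    )
    if expected_kind == "categorical":
        raster: Raster = CategoricalRaster(
            grid=grid,
            codes=np.round(body).astype(np.int32),
            legend={int(k): v for k, v in meta["legend"].items()},
            nodata_code=int(meta["nodata_code"]),
        )
    else:
        nodata = float(meta.get("nodata", CONTINUOUS_NODATA))
        values = np.where(body == nodata, np.nan, body)
        raster = ContinuousRaster(grid=grid, values=values)
    n_valid = raster.n_valid()
    logger.debug("read %s: %d/%d valid cells", path, n_valid, n_rows * n_cols)
    return raster


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _axis_overlap(src_start: np.ndarray, src_end: np.ndarray, tgt_start: np.ndarray, tgt_end: np.ndarray) -> np.ndarray:
    """Dense (n_tgt, n_src) matrix of 1-D interval overlap lengths."""
    lo = np.maximum(tgt_start[:, None], src_start[None, :])
    hi = np.minimum(tgt_end[:, None], src_end[None, :])
    return np.clip(hi - lo, 0.0, None)


def resample_to_grid(layer: Raster, target: GridSpec) -> Raster:
    """Resample onto ``target``: nearest-neighbour (categorical) or
    area-weighted mean (continuous).  Source and target CRS must match."""
    src = layer.grid
    if src.crs_id != target.crs_id:
        raise GeodataError(f"CRS mismatch: {src.crs_id!r} vs {target.crs_id!r} (reprojection out of scope)")
    # extent overlap check
    sx0, sx1 = src.origin_x, src.origin_x + src.n_cols * src.cell_size
    sy1, sy0 = src.origin_y, src.origin_y - src.n_rows * src.cell_size
    tx0, tx1 = target.origin_x, target.origin_x + target.n_cols * target.cell_size
    ty1, ty0 = target.origin_y, target.origin_y - target.n_rows * target.cell_size
    if min(sx1, tx1) <= max(sx0, tx0) or min(sy1, ty1) <= max(sy0, ty0):
        raise GeodataError("source and target grids do not overlap")

    if isinstance(layer, CategoricalRaster):
        cx, cy = target.cell_centers()
        row, col, ok = src.index_of(cx.ravel(), cy.ravel())
        out = np.full(target.n_rows * target.n_cols, layer.nodata_code, dtype=np.int32)
        out[ok] = layer.codes[row[ok], col[ok]]
        return CategoricalRaster(
            grid=target, codes=out.reshape(target.shape), legend=dict(layer.legend), nodata_code=layer.nodata_code
        )

    # continuous: exact area-weighted mean via separable 1-D overlaps
    src_x0 = src.origin_x + np.arange(src.n_cols) * src.cell_size
    tgt_x0 = target.origin_x + np.arange(target.n_cols) * target.cell_size
    wc = _axis_overlap(src_x0, src_x0 + src.cell_size, tgt_x0, tgt_x0 + target.cell_size)
    # rows: use negative y so intervals increase with index
    src_y0 = -src.origin_y + np.arange(src.n_rows) * src.cell_size
    tgt_y0 = -target.origin_y + np.arange(target.n_rows) * target.cell_size
    wr = _axis_overlap(src_y0, src_y0 + src.cell_size, tgt_y0, tgt_y0 + target.cell_size)
    vals = np.where(np.isnan(layer.values), 0.0, layer.values)
    weight = (~np.isnan(layer.values)).astype(float)
    num = wr @ vals @ wc.T
    den = wr @ weight @ wc.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out_vals = np.where(den > 0, num / den, np.nan)
    return ContinuousRaster(grid=target, values=out_vals)


# ---------------------------------------------------------------------------
# Polygon rasterization
# ---------------------------------------------------------------------------


def rasterize_polygons(
    features: Sequence[tuple[int, str, BaseGeometry]],
    grid: GridSpec,
) -> CategoricalRaster:
    """Burn polygons into a categorical raster by cell-centre containment.

    ``features`` is a sequence of ``(id, name, geometry)``; ids must be
    positive and unique.  Cells whose centre lies in no polygon get nodata;
    a centre covered by several polygons goes to the smallest id (logged).
    """
    ids = [f[0] for f in features]
    if any(i <= 0 for i in ids):
        raise GeodataError("polygon ids must be positive")
    if len(set(ids)) != len(ids):
        raise GeodataError("polygon ids must be unique")
    for pid, name, geom in features:
        if not geom.is_valid:
            raise GeodataError(f"polygon {pid} ({name}) is invalid (self-intersecting?)")
    out = np.full(grid.shape, DEFAULT_NODATA_CODE, dtype=np.int32)
    cx, cy = grid.cell_centers()
    overlaps = 0
    for pid, _name, geom in sorted(features, key=lambda f: f[0]):
        inside = shapely.intersects_xy(geom, cx, cy)
        taken = inside & (out != DEFAULT_NODATA_CODE)
        overlaps += int(taken.sum())
        out[inside & (out == DEFAULT_NODATA_CODE)] = pid
    if overlaps:
        logger.warning("rasterize_polygons: %d cell centres covered by >1 polygon; smallest id kept", overlaps)
    return CategoricalRaster(grid=grid, codes=out, legend={pid: name for pid, name, _ in features})


# ---------------------------------------------------------------------------
# GeoJSON vectors
# ---------------------------------------------------------------------------


def write_geojson(features: Iterable[tuple[BaseGeometry, dict]], path: str | Path) -> Path:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": geom_mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    path.write_text(json.dumps(fc), encoding="utf-8")
    return path


def read_geojson(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    path = Path(path)
    if not path.exists():
        raise GeodataError(f"vector file does not exist: {path}")
    fc = json.loads(path.read_text(encoding="utf-8"))
    if fc.get("type") != "FeatureCollection":
        raise GeodataError(f"{path} is not a GeoJSON FeatureCollection")
    return [(geom_shape(f["geometry"]), dict(f.get("properties") or {})) for f in fc["features"]]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One run's parameters (seed, grid, budgets, production)."""

    seed: int
    grid: GridSpec
    ri_floor: float = 0.05
    flii_threshold: float = 6.0
    pasture_area_budget_ha: float = 0.0
    national_production_t: float = 100_000.0
    occupation_years: float = 1.0
    msa_params_path: str | None = None
    landscape: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)
    trade: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ri_floor > 0:
            raise GeodataError(f"ri_floor must be positive, got {self.ri_floor}")
        if self.pasture_area_budget_ha < 0:
            raise GeodataError("pasture_area_budget_ha must be non-negative")
        if not self.national_production_t > 0:
            raise GeodataError("national_production_t must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise GeodataError(f"config file does not exist: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise GeodataError(f"config {path} is not a mapping")
    try:
        grid = GridSpec(**raw.pop("grid"))
        return RunConfig(grid=grid, **raw)
    except (KeyError, TypeError) as exc:
        raise GeodataError(f"invalid config {path}: {exc}") from exc


def log_area(step: str, mask: np.ndarray, grid: GridSpec) -> float:
    """Log and return the area (ha) of a boolean cell mask — audit helper."""
    ha = float(mask.sum()) * grid.cell_area_ha
    logger.info("%s: %.2f ha (%d cells)", step, ha, int(mask.sum()))
    return ha
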