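"""End-to-end orchestration: synth -> harmonize -> msa -> importance -> impact -> trade.

Each stage writes its outputs under ``<outdir>/<stage>/``; with ``resume=True``
a stage whose outputs already exist is reloaded instead of recomputed.  One
global seed fans out into per-stage substreams keyed by stage name, so
changing one stage's parameters never perturbs another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import shapely

from bioscape import biodiversity_importance as bio_imp
from bioscape import impact_metrics as im
from bioscape import msa_model as msa
from bioscape import supplychain_attribution as sca
from bioscape import synthetic_landscape as synth
from bioscape.geodata_io import (
    CategoricalRaster,
    ContinuousRaster,
    GeodataError,
    RunConfig,
    load_config,
    read_geojson,
    read_raster,
    write_geojson,
    write_raster,
)
from bioscape.landuse_harmonizer import COCOA_TYPE_LEGEND, LandUseRaster, harmonize
from bioscape.synthetic_landscape import BINARY_LEGEND, LandscapeBundle, SyntheticSpecies

logger = logging.getLogger("bioscape.pipeline")

STAGES = ("synth", "harmonize", "msa", "importance", "impact", "trade")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Per-stage substream keyed by stage name (stable across runs)."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineState:
    cfg: RunConfig
    outdir: Path
    bundle: LandscapeBundle | None = None
    species: list[SyntheticSpecies] | None = None
    landuse: LandUseRaster | None = None
    msa_layers: msa.MSALayers | None = None
    msa_loss: ContinuousRaster | None = None
    ri: ContinuousRaster | None = None
    rwr: ContinuousRaster | None = None
    yield_raster: ContinuousRaster | None = None
    bim_total_raster: ContinuousRaster | None = None
    bim_cocoa_raster: ContinuousRaster | None = None
    bf_raster: ContinuousRaster | None = None
    bim_total_sum: float = 0.0
    bim_cocoa_sum: float = 0.0
    dept_raster: CategoricalRaster | None = None
    dept_table: pd.DataFrame | None = None
    flows: pd.DataFrame | None = None
    trade_skipped: bool = False
    outputs: dict[str, list[Path]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

_SYNTH_RASTERS = {
    "base_landcover": "categorical",
    "cocoa_presence": "categorical",
    "cocoa_shade_hint": "categorical",
    "forest_management": "categorical",
    "forest_integrity": "continuous",
    "livestock_density": "continuous",
    "pnv": "categorical",
    "suitability": "continuous",
    "dem": "continuous",
}


def stage_synth(state: PipelineState) -> None:
    cfg = state.cfg
    d = state.outdir / "synth"
    paths = {name: d / f"{name}.asc" for name in _SYNTH_RASTERS}
    roads_p, depts_p, species_p = d / "roads.geojson", d / "departments.geojson", d / "species.geojson"

    bundle = synth.generate_landscape(
        stage_seed(cfg.seed, "synth"), cfg.grid, **cfg.landscape
    )
    species_kwargs = {"n_species": 20, **cfg.species}
    species = synth.generate_species(
        stage_seed(cfg.seed, "species"), grid=cfg.grid, dem=bundle.dem, **species_kwargs
    )
    for name in _SYNTH_RASTERS:
        write_raster(getattr(bundle, name), paths[name])
    write_geojson([(r, {"id": i}) for i, r in enumerate(bundle.roads)], roads_p)
    write_geojson([(g, {"id": pid, "name": nm}) for pid, nm, g in bundle.departments], depts_p)
    write_geojson(synth.species_to_features(species, cfg.grid), species_p)
    state.bundle, state.species = bundle, species
    state.outputs["synth"] = [*paths.values(), roads_p, depts_p, species_p]


def load_synth(state: PipelineState) -> None:
    cfg = state.cfg
    d = state.outdir / "synth"
    layers = {name: read_raster(d / f"{name}.asc", kind) for name, kind in _SYNTH_RASTERS.items()}
    roads = [g for g, _ in read_geojson(d / "roads.geojson")]
    departments = [(int(p["id"]), str(p["name"]), g) for g, p in read_geojson(d / "departments.geojson")]
    state.bundle = LandscapeBundle(grid=cfg.grid, roads=roads, departments=departments, **layers)
    species = []
    cx, cy = cfg.grid.cell_centers()
    for geom, props in read_geojson(d / "species.geojson"):
        mask = shapely.intersects_xy(geom, cx, cy)  # dissolved cell boxes -> exact
        species.append(
            SyntheticSpecies(
                species_id=str(props["id"]),
                range_mask=mask,
                elevation_min=float(props["elevation_min"]),
                elevation_max=float(props["elevation_max"]),
                global_range_area_ha=float(props["global_range_area"]),
            )
        )
    state.species = species


def stage_harmonize(state: PipelineState) -> None:
    d = state.outdir / "harmonize"
    lu = harmonize(state.bundle, state.cfg)
    state.landuse = lu
    grid = state.cfg.grid
    cocoa_mask_r = CategoricalRaster(grid=grid, codes=lu.cocoa_mask.astype(np.int32), legend=dict(BINARY_LEGEND))
    cocoa_type_r = CategoricalRaster(grid=grid, codes=lu.cocoa_type.astype(np.int32), legend=dict(COCOA_TYPE_LEGEND))
    outs = [
        write_raster(lu.landuse, d / "landuse.asc"),
        write_raster(cocoa_mask_r, d / "cocoa_mask.asc"),
        write_raster(cocoa_type_r, d / "cocoa_type.asc"),
    ]
    audit_p = d / "allocation_audit.csv"
    pd.DataFrame(lu.audit).to_csv(audit_p, index=False)
    state.outputs["harmonize"] = [*outs, audit_p]


def load_harmonize(state: PipelineState) -> None:
    d = state.outdir / "harmonize"
    lu = read_raster(d / "landuse.asc", "categorical")
    cocoa_mask = read_raster(d / "cocoa_mask.asc", "categorical").codes == 1
    cocoa_type = read_raster(d / "cocoa_type.asc", "categorical").codes.astype(np.int8)
    state.landuse = LandUseRaster(landuse=lu, cocoa_mask=cocoa_mask, cocoa_type=cocoa_type)


def _msa_params(state: PipelineState) -> msa.MSAParams:
    if state.cfg.msa_params_path:
        return msa.MSAParams.from_yaml(state.cfg.msa_params_path)
    return msa.MSAParams()


def stage_msa(state: PipelineState) -> None:
    d = state.outdir / "msa"
    params = _msa_params(state)
    layers = msa.compute_msa(state.landuse, state.bundle.roads, params)
    loss = msa.msa_loss_cocoa(state.landuse, state.bundle.roads, params)
    state.msa_layers, state.msa_loss = layers, loss
    outs = [
        write_raster(layers.msa_lu, d / "msa_lu.asc"),
        write_raster(layers.msa_infra, d / "msa_infra.asc"),
        write_raster(layers.msa_frag, d / "msa_frag.asc"),
        write_raster(layers.msa_total, d / "msa_total.asc"),
        write_raster(loss, d / "msa_loss.asc"),
    ]
    summary_p = d / "summary.json"
    vals = layers.msa_total.values
    summary_p.write_text(
        json.dumps({"area_weighted_mean_msa": float(np.nanmean(vals))}), encoding="utf-8"
    )
    state.outputs["msa"] = [*outs, summary_p]


def load_msa(state: PipelineState) -> None:
    d = state.outdir / "msa"
    state.msa_layers = msa.MSALayers(
        msa_lu=read_raster(d / "msa_lu.asc", "continuous"),
        msa_infra=read_raster(d / "msa_infra.asc", "continuous"),
        msa_frag=read_raster(d / "msa_frag.asc", "continuous"),
        msa_total=read_raster(d / "msa_total.asc", "continuous"),
    )
    state.msa_loss = read_raster(d / "msa_loss.asc", "continuous")


def stage_importance(state: PipelineState) -> None:
    d = state.outdir / "importance"
    cfg = state.cfg
    dem = state.bundle.dem
    rasters = [bio_imp.species_rwr(sp, dem, cfg.grid) for sp in state.species]
    rwr = bio_imp.aggregate_rwr(rasters)
    # terrestrial valid-cell set: water cells carry no score
    water = state.bundle.base_landcover.mask_of("water")
    rwr_vals = rwr.values.copy()
    rwr_vals[water] = np.nan
    rwr = ContinuousRaster(grid=cfg.grid, values=rwr_vals)
    ri = bio_imp.rwr_to_ri(rwr, ri_floor=cfg.ri_floor)
    state.rwr, state.ri = rwr, ri
    state.outputs["importance"] = [
        write_raster(rwr, d / "rwr.asc"),
        write_raster(ri, d / "ri.asc"),
    ]


def load_importance(state: PipelineState) -> None:
    d = state.outdir / "importance"
    state.rwr = read_raster(d / "rwr.asc", "continuous")
    state.ri = read_raster(d / "ri.asc", "continuous")


def stage_impact(state: PipelineState) -> None:
    d = state.outdir / "impact"
    cfg = state.cfg
    grid = cfg.grid
    lu = state.landuse
    from bioscape.geodata_io import rasterize_polygons

    state.dept_raster = rasterize_polygons(state.bundle.departments, grid)
    bim_total_r, state.bim_total_sum = im.bim_total(state.msa_layers.msa_total, state.ri, grid)
    state.bim_total_raster = bim_total_r
    if lu.cocoa_mask.any():
        yr = im.downscale_yield(
            state.bundle.suitability, lu.cocoa_mask, cfg.national_production_t, cfg.occupation_years
        )
        bim_cocoa_r, state.bim_cocoa_sum = im.bim_cocoa(state.msa_loss, state.ri, lu.cocoa_mask, grid)
        bf_r = im.bf_cocoa(bim_cocoa_r, yr, cfg.occupation_years)
    else:
        logger.warning("zero cocoa cells: yields and BF undefined, bim_cocoa = 0")
        yr = ContinuousRaster(grid=grid, values=np.zeros(grid.shape))
        bim_cocoa_r, state.bim_cocoa_sum = im.bim_cocoa(
            ContinuousRaster(grid=grid, values=np.zeros(grid.shape)), state.ri, lu.cocoa_mask, grid
        )
        bf_r = ContinuousRaster(grid=grid, values=np.full(grid.shape, np.nan))
    state.yield_raster, state.bim_cocoa_raster, state.bf_raster = yr, bim_cocoa_r, bf_r
    table = im.department_aggregate(
        state.dept_raster, lu, bf_r, bim_cocoa_r, bim_total_r, yr, cfg.occupation_years
    )
    # production-weighted variant alongside, for mass-consistent attribution
    wtable = im.department_aggregate(
        state.dept_raster, lu, bf_r, bim_cocoa_r, bim_total_r, yr, cfg.occupation_years, weighted=True
    )
    table["bf_all_weighted"] = wtable["bf_all"]
    state.dept_table = table
    outs = [
        write_raster(yr, d / "yield.asc"),
        write_raster(bim_total_r, d / "bim_total.asc"),
        write_raster(bim_cocoa_r, d / "bim_cocoa.asc"),
        write_raster(bf_r, d / "bf.asc"),
        write_raster(state.dept_raster, d / "departments.asc"),
    ]
    table_p = d / "departments.csv"
    table.to_csv(table_p)
    state.outputs["impact"] = [*outs, table_p]


def load_impact(state: PipelineState) -> None:
    d = state.outdir / "impact"
    state.yield_raster = read_raster(d / "yield.asc", "continuous")
    state.bim_total_raster = read_raster(d / "bim_total.asc", "continuous")
    state.bim_cocoa_raster = read_raster(d / "bim_cocoa.asc", "continuous")
    state.bf_raster = read_raster(d / "bf.asc", "continuous")
    state.dept_raster = read_raster(d / "departments.asc", "categorical")
    state.dept_table = pd.read_csv(d / "departments.csv", index_col="department_id")
    state.bim_total_sum = float(np.nansum(state.bim_total_raster.values))
    state.bim_cocoa_sum = float(np.nansum(state.bim_cocoa_raster.values))


def stage_trade(state: PipelineState) -> None:
    d = state.outdir / "trade"
    cfg = state.cfg
    table = state.dept_table
    if state.landuse is not None and not state.landuse.cocoa_mask.any():
        logger.warning("trade stage skipped: no cocoa production to attribute")
        state.trade_skipped = True
        state.outputs["trade"] = []
        return
    spec = synth.SyntheticTradeSpec(**cfg.trade)
    producing = table[table.production_t > 0]
    trade = synth.generate_trade(
        stage_seed(cfg.seed, "trade"),
        {int(i): float(p) for i, p in producing.production_t.items()},
        spec,
    )
    flows = sca.attribute_flows(trade, table)
    state.flows = flows
    exporters = sca.aggregate_by("exporter", flows)
    importers = sca.aggregate_by("importer", flows)
    d.mkdir(parents=True, exist_ok=True)
    trade_p, flows_p = d / "trade.csv", d / "flows.csv"
    exp_p, imp_p, sankey_p = d / "exporters.csv", d / "importers.csv", d / "sankey.csv"
    trade.to_csv(trade_p, index=False)
    flows.to_csv(flows_p, index=False)
    exporters.to_csv(exp_p)
    importers.to_csv(imp_p)
    # Sankey-ready edge list: department -> exporter and exporter -> importer
    left = flows.groupby(["department_id", "exporter"], as_index=False).bim.sum()
    left.columns = ["source", "target", "bim"]
    right = flows.groupby(["exporter", "importer"], as_index=False).bim.sum()
    right.columns = ["source", "target", "bim"]
    pd.concat([left, right], ignore_index=True).to_csv(sankey_p, index=False)
    state.outputs["trade"] = [trade_p, flows_p, exp_p, imp_p, sankey_p]


def load_trade(state: PipelineState) -> None:
    d = state.outdir / "trade"
    if not (d / "flows.csv").exists():
        state.trade_skipped = True
        return
    state.flows = pd.read_csv(d / "flows.csv")


_STAGE_FUNCS: dict[str, tuple[Callable, Callable, list[str]]] = {
    "synth": (stage_synth, load_synth, ["synth/base_landcover.asc", "synth/species.geojson"]),
    "harmonize": (stage_harmonize, load_harmonize, ["harmonize/landuse.asc"]),
    "msa": (stage_msa, load_msa, ["msa/msa_total.asc", "msa/msa_loss.asc"]),
    "importance": (stage_importance, load_importance, ["importance/ri.asc"]),
    "impact": (stage_impact, load_impact, ["impact/departments.csv"]),
    "trade": (stage_trade, load_trade, ["trade/flows.csv"]),
}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_pipeline(
    config_path: str | Path,
    outdir: str | Path,
    resume: bool = False,
    stop_after: str | None = None,
) -> dict:
    """Execute the pipeline; returns (and writes) the run summary."""
    cfg = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(cfg=cfg, outdir=outdir)
    for stage in STAGES:
        run_fn, load_fn, markers = _STAGE_FUNCS[stage]
        cached = resume and all((outdir / m).exists() for m in markers)
        try:
            if cached:
                logger.info("stage %s: reusing cached outputs", stage)
                load_fn(state)
            else:
                logger.info("stage %s: running", stage)
                run_fn(state)
        except Exception as exc:  # partial outputs retained for inspection
            raise StageFailure(stage, exc) from exc
        if stage == stop_after:
            break
    summary = build_summary(state, config_path)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")
    return summary


def build_summary(state: PipelineState, config_path: str | Path) -> dict:
    cfg = state.cfg
    checksums = {}
    for stage in STAGES:
        sd = state.outdir / stage
        if sd.is_dir():
            for p in sorted(sd.iterdir()):
                if p.is_file():
                    checksums[f"{stage}/{p.name}"] = _sha256(p)
    cocoa_area_bim = float("nan")
    if state.bim_total_raster is not None and state.landuse is not None and state.landuse.cocoa_mask.any():
        cocoa_area_bim = float(np.nansum(state.bim_total_raster.values[state.landuse.cocoa_mask]))
    summary = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(Path(config_path).read_bytes()).hexdigest(),
        "bim_total": state.bim_total_sum,
        "bim_cocoa": state.bim_cocoa_sum,
        "cocoa_share_of_cocoa_area_impacts": (
            state.bim_cocoa_sum / cocoa_area_bim if cocoa_area_bim and cocoa_area_bim > 0 else None
        ),
        "trade_skipped": state.trade_skipped,
        "checksums": checksums,
    }
    if state.flows is not None:
        summary["flow_summary"] = sca.flow_summary(state.flows)
    return summary
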