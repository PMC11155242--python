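"""Attribute department biodiversity factors to trade flows.

Traced rows get their department's BF; UNKNOWN-origin rows get a BF averaged
over departments, weighted by each department's untraced volume (production
minus traced volume, floored at zero — the only mass-consistent
reconstruction from the available fields).  Aggregations by exporter or
importer preserve the grand total exactly; DOMESTIC rows carry impacts but
stay out of importer rankings.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from bioscape.geodata_io import GeodataError
from bioscape.synthetic_landscape import DOMESTIC, UNKNOWN

logger = logging.getLogger("bioscape.supplychain_attribution")

TRADE_COLUMNS = ["department_id", "exporter", "importer", "volume_t"]


def _check_trade(trade: pd.DataFrame) -> None:
    missing = set(TRADE_COLUMNS) - set(trade.columns)
    if missing:
        raise GeodataError(f"trade table missing columns {sorted(missing)}")
    if (trade.volume_t < 0).any():
        raise GeodataError("trade volumes must be non-negative")


def untraced_volumes(dept_table: pd.DataFrame, trade: pd.DataFrame) -> pd.Series:
    """Per-department untraced volume u_d = max(0, production_d − traced_d)."""
    traced = trade[trade.department_id != UNKNOWN]
    traced_by_dept = traced.groupby("department_id").volume_t.sum()
    traced_by_dept.index = traced_by_dept.index.astype(dept_table.index.dtype)
    u = dept_table["production_t"].sub(traced_by_dept, fill_value=0.0).clip(lower=0.0)
    return u


def untraced_bf(
    dept_table: pd.DataFrame,
    trade: pd.DataFrame,
    bf_column: str = "bf_all",
) -> float:
    """Untraced-volume-weighted average BF: Σ_d w_d · BF_d, w_d = u_d / Σ u.

    With no UNKNOWN rows the untraced average is unused; a plain
    production-weighted BF is returned with a warning.  UNKNOWN rows with
    zero total untraced volume are a mass imbalance and raise.
    """
    _check_trade(trade)
    if bf_column not in dept_table.columns:
        raise GeodataError(f"department table has no column {bf_column!r}")
    has_unknown = (trade.department_id == UNKNOWN).any()
    bf = dept_table[bf_column]
    ok = bf.notna()
    if not has_unknown:
        warnings.warn(
            "no UNKNOWN rows: returning production-weighted BF instead of the untraced average",
            stacklevel=2,
        )
        w = dept_table.loc[ok, "production_t"]
        return float((bf[ok] * w).sum() / w.sum())
    u = untraced_volumes(dept_table, trade)
    u = u[ok.reindex(u.index, fill_value=False)]
    if u.sum() <= 0:
        raise GeodataError("UNKNOWN rows present but no department has untraced volume (mass imbalance)")
    w = u / u.sum()
    return float((bf.loc[w.index] * w).sum())


def attribute_flows(
    trade: pd.DataFrame,
    dept_table: pd.DataFrame,
    bf_column: str = "bf_all",
) -> pd.DataFrame:
    """Add per-row impact: bim = volume × BF_department (or × untraced BF)."""
    _check_trade(trade)
    flows = trade.copy()
    known = flows.department_id != UNKNOWN
    known_ids = set(flows.loc[known, "department_id"].astype(dept_table.index.dtype))
    missing = known_ids - set(dept_table.index)
    if missing:
        raise GeodataError(f"departments {sorted(missing)} absent from the impact table")
    bf_map = dept_table[bf_column]
    flows["bf_applied"] = np.nan
    flows.loc[known, "bf_applied"] = (
        flows.loc[known, "department_id"].astype(dept_table.index.dtype).map(bf_map).to_numpy()
    )
    if (~known).any():
        flows.loc[~known, "bf_applied"] = untraced_bf(dept_table, trade, bf_column)
    if flows.bf_applied.isna().any():
        bad = flows.loc[flows.bf_applied.isna(), "department_id"].unique()
        raise GeodataError(f"no BF available for departments {sorted(map(str, bad))}")
    flows["bim"] = flows.volume_t * flows.bf_applied
    flows["traced_flag"] = known
    return flows


def aggregate_by(actor: str, flows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate attributed flows per exporter or importer.

    Importer aggregation drops DOMESTIC rows.  Columns: volume_t, bim,
    bf_per_ton (absent for zero-volume actors), traced_share.
    """
    if actor not in ("exporter", "importer"):
        raise GeodataError("actor must be 'exporter' or 'importer'")
    if flows.empty:
        raise GeodataError("no flows to aggregate")
    if "bim" not in flows.columns:
        raise GeodataError("flows not attributed yet (no bim column)")
    sub = flows if actor == "exporter" else flows[flows.importer != DOMESTIC]
    grouped = sub.groupby(actor).apply(
        lambda g: pd.Series(
            {
                "volume_t": g.volume_t.sum(),
                "bim": g.bim.sum(),
                "traced_share": (g.bim[g.traced_flag].sum() / g.bim.sum()) if g.bim.sum() > 0 else np.nan,
            }
        ),
        include_groups=False,
    )
    grouped["bf_per_ton"] = np.where(grouped.volume_t > 0, grouped.bim / grouped.volume_t, np.nan)
    return grouped.sort_values("bim", ascending=False)


def flow_summary(flows: pd.DataFrame) -> dict:
    """Headline ratios: totals, export share of impacts, traced ratios.

    Both traceability denominators are reported (production-level tracing is
    ambiguous between production and exports in the source material).
    """
    total_bim = float(flows.bim.sum())
    exported = flows[flows.importer != DOMESTIC]
    traced = flows[flows.traced_flag]
    traced_exported = exported[exported.traced_flag]
    return {
        "total_bim": total_bim,
        "total_volume_t": float(flows.volume_t.sum()),
        "export_bim": float(exported.bim.sum()),
        "export_share_of_bim": float(exported.bim.sum() / total_bim) if total_bim > 0 else float("nan"),
        "traced_share_of_volume": float(traced.volume_t.sum() / flows.volume_t.sum()),
        "traced_share_of_export_volume": (
            float(traced_exported.volume_t.sum() / exported.volume_t.sum())
            if len(exported) and exported.volume_t.sum() > 0
            else float("nan")
        ),
    }
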