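"""Readers and writers for the tidy delimited tables the pipeline uses.

Trace tables are one row per cell x timepoint; lag tables are one row per
cell (compatible with archived single-cell lag exports); plate tables may
be tidy (well_id, time_min, absorbance) or wide (a time column plus one
column per well) with a separate well-metadata table; abundance tables are
long format (protein, system, role, condition, mean_copies).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import CellTrace, LagRecord, PlateCurve, TraceSet

__all__ = [
    "read_trace_table", "write_trace_table",
    "read_lag_table", "write_lag_table",
    "read_plate_table", "write_plate_table",
    "read_abundance_table",
]

TRACE_COLUMNS = ["cell_id", "parent_id", "experiment_id", "condition",
                 "time_min", "length", "gfp_molecules", "division_flag"]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_trace_table(traces: Iterable[CellTrace], path) -> None:
    rows = []
    for tr in traces:
        for t, ln, fl, dv in zip(tr.times, tr.lengths, tr.fluorescence,
                                 tr.division_flag):
            rows.append((tr.cell_id, tr.parent_id if tr.parent_id else "",
                         tr.experiment_id, tr.condition, t, ln, fl, int(dv)))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, index=False, sep=_sep(path))


def read_trace_table(path) -> TraceSet:
    df = pd.read_csv(path, sep=_sep(path))
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_min")
        parent = grp["parent_id"].iloc[0]
        parent = None if pd.isna(parent) or parent == "" else str(parent)
        traces.append(CellTrace(
            cell_id=str(cid), parent_id=parent,
            experiment_id=str(grp["experiment_id"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            times=grp["time_min"].to_numpy(float),
            lengths=grp["length"].to_numpy(float),
            fluorescence=grp["gfp_molecules"].to_numpy(float),
            division_flag=grp["division_flag"].to_numpy().astype(bool)))
    return TraceSet(traces)


# accepted aliases for lag-table columns, to stay compatible with archived
# single-cell lag exports whose headers differ in case and wording
_LAG_ALIASES = {
    "cell_id": ["cell_id", "cell", "id", "cell_name"],
    "condition": ["condition", "cond", "medium", "experiment_condition"],
    "induction_lag": ["induction_lag", "induction_lag_min", "lag_induction",
                      "induction lag", "lac_induction_lag", "induction_lags"],
    "growth_lag": ["growth_lag", "growth_lag_min", "lag_growth", "growth lag",
                   "growth_lags"],
    "induction_status": ["induction_status", "status_induction"],
    "growth_status": ["growth_status", "status_growth"],
}


def read_lag_table(path) -> pd.DataFrame:
    """Read a per-cell lag table, normalising common column-name variants."""
    df = pd.read_csv(path, sep=_sep(path))
    lower = {c.lower().strip(): c for c in df.columns}
    renames = {}
    for canon, aliases in _LAG_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                renames[lower[alias]] = canon
                break
    df = df.rename(columns=renames)
    if "induction_lag" not in df.columns:
        raise ValueError("lag table has no recognisable induction-lag column; "
                         f"found {list(df.columns)}")
    for col in ("induction_lag", "growth_lag"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_lag_table(records_or_df, path) -> None:
    if isinstance(records_or_df, pd.DataFrame):
        df = records_or_df
    else:
        df = pd.DataFrame([{
            "cell_id": r.cell_id, "condition": r.condition,
            "induction_lag": r.induction_lag,
            "induction_status": r.induction_status,
            "growth_lag": r.growth_lag, "growth_status": r.growth_status,
            "classification": r.classification,
        } for r in records_or_df])
    df.to_csv(path, index=False, sep=_sep(path))


def read_plate_table(path, meta_path=None) -> list[PlateCurve]:
    """Read plate-reader curves from a tidy or wide table.

    Tidy: columns ``well_id, time_min, absorbance``.  Wide: a ``time_min``
    (or ``time``) column plus one column per well.  The optional metadata
    table (``well_id, strain, condition, iptg_control, replicate``) is
    joined on well id.
    """
    df = pd.read_csv(path, sep=_sep(path))
    meta = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep=_sep(meta_path))
        meta = {str(r["well_id"]): r for _, r in mdf.iterrows()}

    def build(well, times, absorbance):
        m = meta.get(str(well), {})
        get = (lambda k, d: m[k] if k in m else d)
        return PlateCurve(
            well_id=str(well), times=np.asarray(times, float),
            absorbance=np.asarray(absorbance, float),
            strain=str(get("strain", "")), condition=str(get("condition", "")),
            iptg_control=bool(get("iptg_control", False)),
            replicate=str(get("replicate", "")))

    cols = {c.lower(): c for c in df.columns}
    if {"well_id", "absorbance"}.issubset(cols):
        tcol = cols.get("time_min", cols.get("time"))
        curves = []
        for well, grp in df.groupby(cols["well_id"], sort=False):
            grp = grp.sort_values(tcol)
            curves.append(build(well, grp[tcol], grp[cols["absorbance"]]))
        return curves
    tcol = cols.get("time_min", cols.get("time"))
    if tcol is None:
        raise ValueError("plate table needs a time_min/time column")
    times = df[tcol].to_numpy(float)
    return [build(c, times, df[c]) for c in df.columns if c != tcol]


def write_plate_table(curves: Iterable[PlateCurve], path,
                      meta_path=None) -> None:
    curves = list(curves)
    rows = []
    for c in curves:
        for t, a in zip(c.times, c.absorbance):
            rows.append((c.well_id, t, a))
    pd.DataFrame(rows, columns=["well_id", "time_min", "absorbance"]).to_csv(
        path, index=False, sep=_sep(path))
    if meta_path is not None:
        pd.DataFrame([{
            "well_id": c.well_id, "strain": c.strain, "condition": c.condition,
            "iptg_control": c.iptg_control, "replicate": c.replicate,
        } for c in curves]).to_csv(meta_path, index=False, sep=_sep(meta_path))


def read_abundance_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    req = {"protein", "system", "role", "condition", "mean_copies"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    df["mean_copies"] = pd.to_numeric(df["mean_copies"])
    if (df["mean_copies"] < 0).any() or not np.isfinite(df["mean_copies"]).all():
        raise ValueError("mean_copies must be non-negative and finite")
    return df
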