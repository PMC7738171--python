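"""Transcriptional memory: inherited molecules, stratified lag fractions,
per-experiment fluorescence centring and the FLCS GFP-positive call.

The inherited-molecule estimate is pure dilution bookkeeping: trace the
lineage back to its ancestor's maximum reporter level Lm during the first
lactose exposure, count the divisions nd since that time, and take
Lm / 2^nd.  This is a lower bound — it assumes no degradation and even
partitioning, and corrects for neither photobleaching nor stochastic
expression during the gap.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CellTrace, FlcsMeasurement, InheritanceEstimate, TraceSet

__all__ = [
    "DEFAULT_BIN_EDGES",
    "lineage_chain",
    "estimate_inherited_molecules",
    "fraction_short_by_inherited",
    "center_fluorescence_by_experiment",
    "compare_groups",
    "classify_flcs_cell",
]

# 8 inherited-molecule groups, log-spaced
DEFAULT_BIN_EDGES = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, math.inf)


def lineage_chain(traces: TraceSet, focal_id: str) -> list[CellTrace]:
    """The ancestor chain root -> focal, following parent links."""
    chain = [traces[focal_id]]
    seen = {focal_id}
    while chain[0].parent_id is not None:
        pid = chain[0].parent_id
        if pid not in traces.traces:
            raise ValueError(f"broken lineage: parent {pid} of "
                             f"{chain[0].cell_id} is missing")
        if pid in seen:
            raise ValueError("lineage contains a cycle")
        seen.add(pid)
        chain.insert(0, traces[pid])
    return chain


def estimate_inherited_molecules(traces: TraceSet, focal_id: str,
                                 first_exposure_window: tuple[float, float],
                                 at_time: float | None = None) -> InheritanceEstimate:
    """Dilution estimate of molecules the focal cell inherited.

    Lm is the maximum fluorescence along the ancestor chain inside the
    first-exposure window and nd the number of divisions between that
    timepoint and the focal cell's observation (``at_time``, default the
    focal cell's first sample).
    """
    chain = lineage_chain(traces, focal_id)
    w0, w1 = first_exposure_window
    if at_time is None:
        at_time = float(traces[focal_id].times[0])
    best_val, best_time = -np.inf, None
    for tr in chain:
        mask = (tr.times >= w0 - 1e-9) & (tr.times <= w1 + 1e-9)
        if not np.any(mask):
            continue
        i = int(np.argmax(tr.fluorescence[mask]))
        val = float(tr.fluorescence[mask][i])
        if val > best_val:
            best_val = val
            best_time = float(tr.times[mask][i])
    if best_time is None:
        raise ValueError(
            f"lineage of {focal_id} has no samples in the first-exposure window")
    nd = 0
    for tr in chain:
        if tr.divides and best_time + 1e-9 < tr.times[-1] < at_time - 1e-9:
            nd += 1
    return InheritanceEstimate(cell_id=focal_id, Lm=best_val, nd=nd)


def fraction_short_by_inherited(records: pd.DataFrame,
                                threshold: float = 50.0,
                                bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
                                naive_fraction: float | None = None) -> pd.DataFrame:
    """Fraction of short lags stratified by inherited molecules.

    ``records`` needs columns ``inherited`` and ``lag`` (measured lags,
    minutes) and optionally ``replicate``.  Returns one row per bin with the
    pooled fraction short, the per-replicate mean and SE when replicates are
    present, and the cell count; empty bins have NaN fractions.
    """
    req = {"inherited", "lag"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    df = records.dropna(subset=["inherited", "lag"]).copy()
    df["short"] = df["lag"] < threshold
    edges = np.asarray(bin_edges, dtype=float)
    df["bin"] = pd.cut(df["inherited"], edges, right=False, include_lowest=True)
    rows = []
    for interval in df["bin"].cat.categories:
        sub = df[df["bin"] == interval]
        row = {
            "bin_left": interval.left,
            "bin_right": interval.right,
            "n_cells": len(sub),
            "fraction_short": sub["short"].mean() if len(sub) else np.nan,
        }
        if "replicate" in df.columns and len(sub):
            per_rep = sub.groupby("replicate", observed=True)["short"].mean()
            row["replicate_mean"] = per_rep.mean()
            row["replicate_se"] = (per_rep.std(ddof=1) / np.sqrt(len(per_rep))
                                   if len(per_rep) > 1 else np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["naive_fraction"] = (naive_fraction if naive_fraction is not None
                                   else df["short"].mean())
    return out


def center_fluorescence_by_experiment(values, experiment_ids) -> np.ndarray:
    """Subtract the per-experiment mean from each value.

    Day-to-day illumination offsets dominate the few-molecule signal of
    interest, so comparisons are made on experiment-centred values; with a
    single experiment this subtracts one global mean.
    """
    values = np.asarray(values, dtype=float)
    s = pd.Series(values)
    return (s - s.groupby(np.asarray(experiment_ids)).transform("mean")).to_numpy()


def compare_groups(centered_values, labels, short_label: str = "short",
                   long_label: str = "long") -> tuple[float, float]:
    """Mean difference (short - long) and one-sided Welch t-test p-value
    for the alternative short > long."""
    centered_values = np.asarray(centered_values, dtype=float)
    labels = np.asarray(labels)
    short = centered_values[labels == short_label]
    long_ = centered_values[labels == long_label]
    if short.size == 0 or long_.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = float(short.mean() - long_.mean())
    res = stats.ttest_ind(short, long_, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    if math.isnan(p) and diff == 0.0:
        p = 0.5  # identical constant groups: exchangeable, t = 0
    return diff, p


def classify_flcs_cell(m: FlcsMeasurement,
                       cpm_fold: float = 2.375,
                       diffusion_bounds: tuple[float, float] = (3.0, 30.0),
                       max_particles: float = 20.0) -> str:
    """Three-criteria GFP-positive call for one FLCS measurement.

    ``gfp_positive`` requires all of: brightness at least ``cpm_fold`` times
    the cohort median (the 5-sigma threshold of the normalised CPM
    distribution), a physically plausible diffusion time (3-30 ms for a
    LacZ-GFP tetramer), and a fitted particle number N <= 20.  Fit-validity
    failures (diffusion time out of range or N > 20) give ``dubious``; a
    valid fit below the brightness threshold gives ``gfp_negative``.
    """
    vals = [m.cpm, m.cpm_cohort_median, m.diffusion_time, m.n_particles]
    if not all(np.isfinite(vals)):
        raise ValueError("non-finite FLCS measurement")
    if m.n_particles > max_particles:
        return "dubious"
    if not diffusion_bounds[0] <= m.diffusion_time <= diffusion_bounds[1]:
        return "dubious"
    if m.cpm >= cpm_fold * m.cpm_cohort_median:
        return "gfp_positive"
    return "gfp_negative"
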