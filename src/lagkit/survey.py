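"""Sensorless-cell survey under Poisson expression noise.

With a Poisson copy-number distribution of mean m, the fraction of cells
with exactly zero copies of a sensor protein is P(N = 0) = exp(-m); it
exceeds 5% whenever the mean is 3 copies/cell or less (e^-3 ~= 0.05).
Systems whose sensor kinase falls at or below that mean in many growth
conditions are expected to harbour sensorless subpopulations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "zero_fraction",
    "sensorless_conditions",
    "reverse_cumulative",
]


def zero_fraction(mean_copies):
    """P(no copies) = exp(-mean) for Poisson-distributed copy numbers."""
    m = np.asarray(mean_copies, dtype=float)
    if np.any(m < 0):
        raise ValueError("mean copy numbers must be >= 0")
    out = np.exp(-m)
    return out if out.ndim else float(out)


def sensorless_conditions(table: pd.DataFrame, threshold_copies: float = 3.0,
                          min_conditions: int = 6,
                          role: str = "kinase") -> pd.DataFrame:
    """Per-system count of conditions with sensor mean <= ``threshold_copies``.

    ``table`` is long-format with columns ``system, role, condition,
    mean_copies``.  Systems with at least ``min_conditions`` qualifying
    conditions are flagged; systems lacking a row for the requested role are
    skipped with a warning.  ``role`` may be set to ``transcription_factor``
    to run the same summary on regulator abundances.
    """
    req = {"system", "role", "condition", "mean_copies"}
    if table.empty or not req.issubset(table.columns):
        raise ValueError(f"table must be non-empty with columns {sorted(req)}")
    rows = []
    for system, grp in table.groupby("system"):
        sensors = grp[grp["role"] == role]
        if sensors.empty:
            warnings.warn(f"system {system}: no {role} row; skipped",
                          stacklevel=2)
            continue
        # one value per condition (mean over multiple sensor proteins)
        per_cond = sensors.groupby("condition")["mean_copies"].mean()
        count = int((per_cond <= threshold_copies).sum())
        rows.append({"system": system,
                     "n_sensorless_conditions": count,
                     "n_conditions": len(per_cond),
                     "flagged": count >= min_conditions})
    return pd.DataFrame(rows)


def reverse_cumulative(values):
    """Reverse CDF across conditions: fraction of values >= x.

    Returns ``(x, frac)`` arrays defining the right-continuous step
    function at the sorted unique values; evaluate elsewhere by the rule
    frac(x) = mean(values >= x).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty values")
    x = np.unique(v)
    frac = np.array([(v >= xi).mean() for xi in x])
    return x, frac
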