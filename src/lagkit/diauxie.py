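"""Plate-reader diauxie analysis: background, alignment, delay curves, lags.

A diauxic growth curve is compared with the same condition supplemented
with IPTG (fully induced, hence no lag).  Each well's background is the
lowest quiet sliding-window mean; curves are aligned so OD = 0.01 at t = 0;
a first-passage map t = f(OD) is built by linear interpolation; the delay
between test and control replicates as a function of OD plateaus at the
population lag, which is read off at the point of smallest derivative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import PlateCurve

__all__ = [
    "BackgroundError",
    "estimate_background",
    "align_curve",
    "time_to_od",
    "delay_curve",
    "population_lag_from_delay",
    "transfer_lag",
]


class BackgroundError(ValueError):
    """No quiet window found; the well cannot be background-corrected."""


def estimate_background(absorbance, window: int = 10,
                        cv_max: float = 0.02) -> float:
    """Lowest mean of the sliding windows whose CV is below ``cv_max``.

    Wells are inoculated dilute enough that at least ~2 h sit below the
    detection limit, so some window of ``window`` consecutive measurements
    is flat; if none qualifies the curve is flagged for exclusion.
    """
    a = pd.Series(np.asarray(absorbance, dtype=float))
    if len(a) < window:
        raise BackgroundError(f"need at least {window} measurements")
    roll = a.rolling(window)
    means = roll.mean()
    cvs = roll.std(ddof=1) / means
    ok = means[cvs < cv_max]
    if ok.empty:
        raise BackgroundError("no sliding window with CV below "
                              f"{cv_max}; curve flagged for exclusion")
    return float(ok.min())


def align_curve(curve: PlateCurve, od_align: float = 0.01,
                window: int = 10, cv_max: float = 0.02) -> PlateCurve:
    """Background-subtract and shift time so OD = ``od_align`` at t = 0.

    The crossing time is found by linear interpolation at the first upward
    crossing of ``od_align``.
    """
    background = curve.background
    if background is None:
        background = estimate_background(curve.absorbance, window, cv_max)
    od = curve.absorbance - background
    above = np.nonzero(od >= od_align)[0]
    if above.size == 0 or above[0] == 0:
        if above.size == 0:
            raise ValueError(
                f"well {curve.well_id}: curve never reaches OD {od_align}")
        t_cross = curve.times[0]
    else:
        i = above[0]
        t0, t1 = curve.times[i - 1], curve.times[i]
        y0, y1 = od[i - 1], od[i]
        t_cross = t0 + (od_align - y0) / (y1 - y0) * (t1 - t0)
    return PlateCurve(
        well_id=curve.well_id, times=curve.times - t_cross,
        absorbance=curve.absorbance, strain=curve.strain,
        condition=curve.condition, iptg_control=curve.iptg_control,
        replicate=curve.replicate, background=background, aligned=True)


def time_to_od(curve: PlateCurve):
    """First-passage map t = f(OD) for an aligned curve.

    Returns a vectorised callable: for each query OD, the first time the
    curve reaches it, linearly interpolated between the bracketing samples
    (later dips are ignored — the map uses the running maximum).  Queries
    above the curve's maximum OD return NaN.
    """
    if not curve.aligned:
        raise ValueError("curve must be aligned first")
    od = curve.od
    run_max = np.maximum.accumulate(od)
    # keep the strictly increasing envelope of the running maximum, with the
    # actual sample values at the points where a new maximum is set
    keep = np.ones(len(od), dtype=bool)
    keep[1:] = run_max[1:] > run_max[:-1]
    xs = run_max[keep]
    ts = curve.times[keep]

    def f(query):
        q = np.asarray(query, dtype=float)
        out = np.interp(q, xs, ts, left=np.nan, right=np.nan)
        # np.interp's left fill triggers only below xs[0]; values above the
        # max must be missing, values below the min are before the record
        out = np.where(q > xs[-1], np.nan, out)
        out = np.where(q < xs[0], np.nan, out)
        return out if out.ndim else float(out)

    f.max_od = float(xs[-1])
    return f


def delay_curve(test_curves, control_curves, od_grid=None,
                capacity_fraction: float = 0.9) -> pd.DataFrame:
    """Mean delay (test - control) and SE as a function of OD.

    ``f(OD)`` is evaluated per replicate; the delay at each OD on the grid
    is the difference of the group means and its SE combines both groups'
    standard errors.  The grid is restricted below ``capacity_fraction``
    of the smallest per-curve maximum OD (the carrying-capacity cutoff).
    """
    if not test_curves or not control_curves:
        raise ValueError("need at least one test and one control replicate")
    fs_test = [time_to_od(c) for c in test_curves]
    fs_ctrl = [time_to_od(c) for c in control_curves]
    od_hi = capacity_fraction * min(f.max_od for f in fs_test + fs_ctrl)
    od_lo = max(max(c.od[0] for c in test_curves + control_curves), 1e-4)
    od_lo = max(od_lo, 0.01)  # curves are aligned at OD = 0.01
    if od_hi <= od_lo:
        raise ValueError("empty overlap of OD ranges")
    if od_grid is None:
        od_grid = np.geomspace(od_lo, od_hi, 200)
    else:
        od_grid = np.asarray(od_grid, dtype=float)
        od_grid = od_grid[(od_grid >= od_lo) & (od_grid <= od_hi)]
        if od_grid.size == 0:
            raise ValueError("empty overlap of OD ranges")
    t_test = np.vstack([f(od_grid) for f in fs_test])
    t_ctrl = np.vstack([f(od_grid) for f in fs_ctrl])

    def group_stats(mat):
        mean = np.nanmean(mat, axis=0)
        n = np.sum(~np.isnan(mat), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(n)
        return mean, np.where(n > 1, se, 0.0)

    m_test, se_test = group_stats(t_test)
    m_ctrl, se_ctrl = group_stats(t_ctrl)
    return pd.DataFrame({
        "od": od_grid,
        "delay": m_test - m_ctrl,
        "se": np.sqrt(se_test ** 2 + se_ctrl ** 2),
    }).dropna(subset=["delay"]).reset_index(drop=True)


def population_lag_from_delay(delay: pd.DataFrame, smooth_window: int = 5,
                              interior_fraction: float = 0.8) -> float:
    """Plateau value of the delay-vs-OD curve (the population lag).

    The delay is smoothed with a centred moving average and differentiated
    with respect to log OD; plateau candidates are the interior grid points
    whose absolute derivative is within 2% of the interior derivative range
    of its minimum.  The delay is flat at zero before the first
    subpopulations resume as well, so among candidates the one at the
    largest OD is returned: the population lag is the delay once every
    subpopulation has resumed growth, i.e. the terminal plateau.  A
    monotone or constant derivative means there is no identifiable plateau;
    a warning is emitted and the endpoint value returned.
    """
    if len(delay) < 10:
        raise ValueError("delay curve needs at least 10 grid points")
    sm = delay["delay"].rolling(smooth_window, center=True, min_periods=1).mean()
    log_od = np.log(delay["od"].to_numpy())
    deriv = np.gradient(sm.to_numpy(), log_od)
    n = len(delay)
    margin = int(round((1.0 - interior_fraction) / 2.0 * n))
    lo, hi = margin, n - margin
    interior = np.abs(deriv[lo:hi])
    cutoff = interior.min() + 0.02 * np.ptp(interior)
    i_min = lo + int(np.nonzero(interior <= cutoff)[0][-1])
    d = np.diff(interior)
    if np.all(d > 0) or np.all(d < 0) or \
            (np.ptp(interior) < 1e-12 and interior.max() > 1e-9):
        warnings.warn("no interior plateau in the delay curve (monotone or "
                      "constant derivative); returning the endpoint value",
                      stacklevel=2)
    return float(sm.iloc[i_min])


def transfer_lag(curve: PlateCurve, od_increase: float = 0.001):
    """Lag after a manual transfer: first time OD exceeds OD(0) + od_increase.

    Returns the interpolated first-passage time, or None when the curve
    never exceeds the increment (censored).
    """
    od = curve.od if curve.background is not None else curve.absorbance
    target = od[0] + od_increase
    above = np.nonzero(od > target)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    y0, y1 = od[i - 1], od[i]
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))
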