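"""Synthetic mother-machine, plate-reader and proteomics data.

This module emulates the statistical structure of a glucose-to-lactose
switch experiment: exponential single-cell growth with division, a complete
growth arrest at the switch whose duration is drawn from a mechanistic
bimodal mixture (cells with nonzero preexisting *lac* expression arrest
briefly; "sensorless" cells with exactly zero molecules arrest for 1-3 h),
LacZ-GFP expression read through autofluorescence noise, halving dilution
of molecules across divisions, and diauxie OD curves with an IPTG-induced
control that lacks the lag.  Every generator returns the observables
together with a ground-truth table so downstream estimators can be scored
against it.

Growth is deterministic and shared across a lineage: with the instantaneous
log-length growth rate g(t) set by the medium schedule (and zero during the
arrest), every cell's length is its birth length times exp(G(t) - G(t_b))
where G is the integral of g.  Divisions fire at the first sampling point
where a cell has doubled; daughters halve the length and start at the next
sampling point, so summed length over daughters is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import CellTrace, LagDistribution, PlateCurve, TraceSet

__all__ = [
    "SimScenario",
    "generate_cell_traces",
    "generate_dilution_lineages",
    "generate_plate_curves",
    "generate_abundance_table",
]

LN2 = math.log(2.0)


@dataclass
class SimScenario:
    """Parameters of a simulated medium-switch experiment.

    Defaults reproduce the canonical study conditions: 49/58-min doubling
    times in the pre- and post-switch media, 3-min sampling, 30% of cells
    holding at least one preexisting reporter molecule (hence a short lag
    under 50 min, drawn from a truncated normal on (5, 50) min), sensorless
    cells lagging uniformly on (60, 180) min, autofluorescence noise of SD
    20 molecule equivalents, and full induction at 3000-6000 molecules.
    """

    pre_switch_doubling_time: float = 49.0     # min
    post_switch_doubling_time: float = 58.0    # min
    switch_time: float = 60.0                  # min
    post_switch_window: float = 240.0          # min observed after the switch
    sampling_interval: float = 3.0             # min
    fraction_nonzero_basal: float = 0.30
    short_lag_loc: float = 25.0                # truncated-normal mean, min
    short_lag_scale: float = 8.0               # truncated-normal SD, min
    short_lag_bounds: tuple = (5.0, 50.0)      # min
    long_lag_bounds: tuple = (60.0, 180.0)     # min
    autofluorescence_sd: float = 20.0          # molecules
    induction_rate: float = 30.0               # molecules/min after the lag
    full_induction_level: float = 4000.0       # molecules, in [3000, 6000]
    mean_basal_molecules: float = 5.0          # mean count in nonzero-basal cells
    length_noise_cv: float = 0.02              # multiplicative length noise
    washout_prob: float = 0.0                  # per post-switch daughter branch
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pre_switch_doubling_time", "post_switch_doubling_time",
            "sampling_interval", "induction_rate", "full_induction_level",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("switch_time", "post_switch_window", "autofluorescence_sd",
                     "length_noise_cv", "washout_prob"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.fraction_nonzero_basal <= 1.0:
            raise ValueError("fraction_nonzero_basal must be in [0, 1]")
        if not self.short_lag_bounds[0] < self.short_lag_bounds[1]:
            raise ValueError("short_lag_bounds must be an increasing interval")
        if not self.long_lag_bounds[0] < self.long_lag_bounds[1]:
            raise ValueError("long_lag_bounds must be an increasing interval")
        if self.mean_basal_molecules < 1:
            raise ValueError("mean_basal_molecules must be >= 1 (it is a count)")

    def draw_lag(self, rng: np.random.Generator, short: bool) -> float:
        if short:
            a = (self.short_lag_bounds[0] - self.short_lag_loc) / self.short_lag_scale
            b = (self.short_lag_bounds[1] - self.short_lag_loc) / self.short_lag_scale
            return float(stats.truncnorm.rvs(
                a, b, loc=self.short_lag_loc, scale=self.short_lag_scale,
                random_state=rng))
        return float(rng.uniform(*self.long_lag_bounds))

    def draw_basal(self, rng: np.random.Generator) -> int:
        # a count >= 1 with the stated mean
        return int(1 + rng.poisson(self.mean_basal_molecules - 1.0))


def _integrated_rate(t: np.ndarray, breaks: list, rates: list) -> np.ndarray:
    """G(t) = integral of a piecewise-constant rate; rates[i] holds on
    [breaks[i], breaks[i+1]) and the last rate extends to infinity."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for i, r in enumerate(rates):
        lo = breaks[i]
        hi = breaks[i + 1] if i + 1 < len(breaks) else np.inf
        out += r * np.clip(np.minimum(t, hi) - lo, 0.0, None)
    return out


class _Segment:
    __slots__ = ("cell_id", "parent", "i0", "i1", "lengths", "divides")

    def __init__(self, cell_id, parent, i0, i1, lengths, divides):
        self.cell_id = cell_id
        self.parent = parent
        self.i0 = i0          # first grid index of the segment
        self.i1 = i1          # last grid index (inclusive)
        self.lengths = lengths  # true lengths at grid[i0..i1]
        self.divides = divides


def _grow_tree(grid: np.ndarray, G: np.ndarray, lineage_id: str,
               init_length: float, init_credit: float,
               track_both_from: float, washout_prob: float,
               rng: np.random.Generator) -> list[_Segment]:
    """Build the segments of one lineage by the doubling-trigger rule.

    ``init_credit`` is the fraction of log-doubling the root has already
    completed at grid[0] (random phase).  Before ``track_both_from`` only one
    daughter is kept at a division (the mother-machine channel); afterwards
    both daughters are tracked, each optionally washed out with probability
    ``washout_prob`` (its branch is truncated at a random time).
    """
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{lineage_id}.{counter[0]}"

    segments: list[_Segment] = []
    # stack entries: (parent_id, i_birth_ref, birth_length, credit, i_first_sample)
    stack = [(None, 0, init_length, init_credit, 0)]
    n = len(grid)
    while stack:
        parent, iref, lb, credit, i0 = stack.pop()
        if i0 >= n:
            continue
        cid = new_id()
        # division at first grid index where accumulated log-growth + credit >= ln 2
        glog = G[i0:] - G[iref] + credit
        idx = np.nonzero(glog >= LN2 - 1e-12)[0]
        lengths_full = lb * np.exp(G[i0:] - G[iref] + credit)
        if idx.size == 0:
            i1 = n - 1
            divides = False
        else:
            i1 = i0 + int(idx[0])
            divides = i1 < n - 1   # a division on the last frame is unobserved
        tracked_both = grid[i0] >= track_both_from
        washed = False
        if tracked_both and washout_prob > 0 and rng.random() < washout_prob:
            # branch leaves the channel at a random time within its span
            i1 = i0 + int(rng.integers(0, i1 - i0 + 1))
            divides = False
            washed = True
        seg = _Segment(cid, parent, i0, i1, lengths_full[: i1 - i0 + 1], divides)
        segments.append(seg)
        if divides and not washed:
            half = seg.lengths[-1] / 2.0
            both = grid[i1] >= track_both_from
            n_daughters = 2 if both else 1
            for _ in range(n_daughters):
                stack.append((cid, i1, half, 0.0, i1 + 1))
    return segments


def _emit_traces(segments: list[_Segment], grid: np.ndarray,
                 molecules_of: Callable[[_Segment], np.ndarray],
                 sc: SimScenario, rng: np.random.Generator,
                 experiment_id: str, condition: str) -> list[CellTrace]:
    traces = []
    for seg in segments:
        times = grid[seg.i0: seg.i1 + 1]
        lengths = seg.lengths.copy()
        if sc.length_noise_cv > 0:
            lengths = lengths * (1.0 + sc.length_noise_cv
                                 * rng.standard_normal(len(lengths)))
            lengths = np.maximum(lengths, 1e-9)
        fluor = np.asarray(molecules_of(seg), dtype=float)
        if sc.autofluorescence_sd > 0:
            fluor = fluor + sc.autofluorescence_sd * rng.standard_normal(len(fluor))
        flags = np.zeros(len(times), dtype=bool)
        flags[-1] = seg.divides
        traces.append(CellTrace(
            cell_id=seg.cell_id, parent_id=seg.parent,
            experiment_id=experiment_id, condition=condition,
            times=times, lengths=lengths, fluorescence=fluor,
            division_flag=flags))
    return traces


def _subtree_totals(segments: list[_Segment], n_grid: int) -> np.ndarray:
    """Summed true length of all tracked cells at each grid index."""
    tot = np.zeros(n_grid)
    for seg in segments:
        tot[seg.i0: seg.i1 + 1] += seg.lengths
    return tot


def generate_cell_traces(scenario: SimScenario, n_cells: int,
                         rng: Optional[np.random.Generator] = None,
                         experiment_id: str = "sim",
                         condition: str = "glucose_to_lactose"):
    """Simulate ``n_cells`` mother-machine lineages through a nutrient switch.

    Each lineage is tracked as a single mother line before the switch and as
    a full binary tree afterwards.  At the switch every cell arrests for a
    lag drawn from the bimodal mechanistic mixture: with probability
    ``fraction_nonzero_basal`` the cell holds a nonzero basal reporter count
    and draws a short lag, otherwise it is sensorless (zero molecules) and
    draws a long one.  After the lag, growth resumes and the lineage's total
    reporter count ramps linearly at ``induction_rate`` up to the full
    induction level; molecules are apportioned to cells in proportion to
    their length, so counts partition at division.

    Returns
    -------
    (TraceSet, pandas.DataFrame)
        The traces and a ground-truth table with one row per lineage:
        ``lineage_id, focal_cell_id, true_lag, basal_molecules, is_short``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sc = scenario
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    dt = sc.sampling_interval
    s = sc.switch_time
    t_end = s + sc.post_switch_window
    grid = dt * np.arange(int(math.floor(t_end / dt + 1e-9)) + 1)

    all_traces: list[CellTrace] = []
    truth_rows = []
    for k in range(n_cells):
        short = rng.random() < sc.fraction_nonzero_basal
        basal = float(sc.draw_basal(rng)) if short else 0.0
        tau = sc.draw_lag(rng, short)
        breaks = [0.0, s, s + tau]
        rates = [LN2 / sc.pre_switch_doubling_time, 0.0,
                 LN2 / sc.post_switch_doubling_time]
        G = _integrated_rate(grid, breaks, rates)
        lineage_id = f"lin{k:04d}"
        credit = float(rng.uniform(0.0, LN2))
        segments = _grow_tree(grid, G, lineage_id, init_length=1.0,
                              init_credit=credit, track_both_from=s,
                              washout_prob=sc.washout_prob, rng=rng)
        totals = _subtree_totals(segments, len(grid))
        m_tot = np.minimum(basal + sc.induction_rate
                           * np.clip(grid - s - tau, 0.0, None),
                           max(basal, sc.full_induction_level))

        def molecules_of(seg, totals=totals, m_tot=m_tot):
            sl = slice(seg.i0, seg.i1 + 1)
            return m_tot[sl] * seg.lengths / totals[sl]

        all_traces.extend(_emit_traces(segments, grid, molecules_of, sc, rng,
                                       experiment_id, condition))
        t_q = dt * math.ceil(s / dt - 1e-9)  # first sample at or after the switch
        focal = next(seg for seg in segments
                     if grid[seg.i0] <= t_q <= grid[seg.i1])
        truth_rows.append({
            "lineage_id": lineage_id,
            "focal_cell_id": focal.cell_id,
            "true_lag": tau,
            "basal_molecules": basal,
            "is_short": short,
        })
    return TraceSet(all_traces), pd.DataFrame(truth_rows)


def generate_dilution_lineages(scenario: SimScenario, glucose_gap: float,
                               n_lineages: int,
                               binomial_partition: bool = False,
                               rng: Optional[np.random.Generator] = None,
                               experiment_id: str = "dilution",
                               condition: str = "lactose_glucose_lactose"):
    """Simulate lactose -> glucose (gap) -> lactose dilution lineages.

    During the first lactose exposure the mother line induces fully (ramp to
    the full induction level).  During the glucose gap expression is off and
    the reporter count halves at every division (or is binomially thinned
    when ``binomial_partition``).  At the second switch, the cell arrests
    with a short lag iff at least one molecule was inherited — the
    single-molecule-trigger rule; a fully diluted cell reverts to the naive
    behaviour (a short lag with probability ``fraction_nonzero_basal``).

    Returns ``(TraceSet, truth)`` where truth has one row per lineage with
    ``Lm`` (the peak level), ``nd`` (divisions since the first exposure),
    ``inherited``, the second-switch lag and its short/long class, plus the
    first-exposure window and second switch time.
    """
    if glucose_gap < 0:
        raise ValueError("glucose_gap must be >= 0")
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    sc = scenario
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    dt = sc.sampling_interval
    # first exposure ends exactly when full induction is reached (rounded up
    # to the grid), so the lineage maximum is attained at a unique timepoint
    t_ramp = sc.full_induction_level / sc.induction_rate
    t_first = dt * math.ceil(t_ramp / dt)
    s2 = t_first + glucose_gap                      # second switch
    t_end = s2 + sc.post_switch_window
    grid = dt * np.arange(int(math.floor(t_end / dt + 1e-9)) + 1)
    r_lac = LN2 / sc.post_switch_doubling_time
    r_glc = LN2 / sc.pre_switch_doubling_time

    all_traces: list[CellTrace] = []
    truth_rows = []
    for k in range(n_lineages):
        lineage_id = f"dil{k:04d}"
        # peak level reached during the first exposure
        Lm = float(sc.full_induction_level)
        # The arrest duration depends on the inherited count, which depends on
        # the divisions before s2 — and those do not depend on the arrest (it
        # starts at s2).  So first place the mother-line divisions up to s2
        # with the exact doubling-trigger rule of _grow_tree (same phase
        # credit), then draw the lag and build the tree.
        breaks0 = [0.0, t_first, s2]
        rates0 = [r_lac, r_glc, 0.0]
        G0 = _integrated_rate(grid, breaks0, rates0)
        credit = float(rng.uniform(0.0, LN2))
        div_times = []          # mother-line division times in (t_first, s2]
        mol_path = []           # realized molecule level after each such division
        mol = Lm
        iref, cr = 0, credit
        for i in range(len(grid) - 1):   # a division on the last frame is unobserved
            if grid[i] >= s2 - 1e-9:
                break
            if G0[i] - G0[iref] + cr >= LN2 - 1e-12:
                if grid[i] > t_first + 1e-9:
                    div_times.append(grid[i])
                    if binomial_partition:
                        mol = float(rng.binomial(int(round(mol)), 0.5))
                    else:
                        mol = mol / 2.0
                    mol_path.append(mol)
                iref, cr = i, 0.0
        n_divs = len(div_times)
        inherited_true = mol
        # single-molecule trigger: any inherited molecule guarantees a short
        # lag; a fully diluted cell behaves like a naive one (fresh basal
        # expression gives it the naive chance of a short lag)
        if inherited_true >= 1.0:
            short = True
        else:
            short = bool(rng.random() < sc.fraction_nonzero_basal)
        tau2 = sc.draw_lag(rng, short)
        breaks = [0.0, t_first, s2, s2 + tau2]
        rates = [r_lac, r_glc, 0.0, r_lac]
        G = _integrated_rate(grid, breaks, rates)
        segments = _grow_tree(grid, G, lineage_id, init_length=1.0,
                              init_credit=credit, track_both_from=s2,
                              washout_prob=sc.washout_prob, rng=rng)
        totals = _subtree_totals(segments, len(grid))
        # lineage-total molecule schedule: ramp, plateau, halvings, re-ramp
        m_tot = np.empty(len(grid))
        pre = grid <= t_first + 1e-9
        m_tot[pre] = np.minimum(sc.induction_rate * grid[pre], Lm)
        level = Lm
        j = 0
        levels = []
        for t in grid[~pre]:
            while j < n_divs and t >= div_times[j] - 1e-9:
                level = mol_path[j]
                j += 1
            if t <= s2 + 1e-9:
                levels.append(level)
            else:
                levels.append(min(inherited_true + sc.induction_rate
                                  * max(0.0, t - s2 - tau2),
                                  sc.full_induction_level))
        m_tot[~pre] = levels

        def molecules_of(seg, totals=totals, m_tot=m_tot):
            sl = slice(seg.i0, seg.i1 + 1)
            return m_tot[sl] * seg.lengths / totals[sl]

        all_traces.extend(_emit_traces(segments, grid, molecules_of, sc, rng,
                                       experiment_id, condition))
        t_q = dt * math.ceil(s2 / dt - 1e-9)
        focal = next(seg for seg in segments
                     if grid[seg.i0] <= t_q <= grid[seg.i1])
        truth_rows.append({
            "lineage_id": lineage_id,
            "focal_cell_id": focal.cell_id,
            "Lm": Lm,
            "nd": n_divs,
            "inherited": inherited_true,
            "true_lag": tau2,
            "is_short": short,
            "switch_time": s2,
            "first_exposure_end": t_first,
        })
    return TraceSet(all_traces), pd.DataFrame(truth_rows)


def generate_plate_curves(lag_distribution: LagDistribution,
                          baseline: float = 0.04,
                          noise_cv: float = 0.01,
                          sampling_interval: float = 2.0,
                          seed: int = 0,
                          n_replicates: int = 3,
                          doubling_glucose: float = 49.0,
                          doubling_lactose: float = 58.0,
                          od_initial: float = 1e-4,
                          od_exhaust: float = 0.05,
                          od_capacity: float = 0.5,
                          n_subpops: int = 100):
    """Simulate paired diauxie / IPTG-control plate-reader curve sets.

    The culture grows on glucose from ``od_initial`` until the glucose is
    exhausted at ``od_exhaust``; each of ``n_subpops`` equally weighted
    subpopulations then arrests for its lag (a quantile of the supplied
    single-cell lag distribution) before resuming on lactose up to
    ``od_capacity``.  The IPTG control set is generated identically with all
    lags set to zero.  Absorbance = baseline + OD * (1 + noise).

    Returns ``(test_curves, control_curves)`` as lists of PlateCurve.
    """
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    from .popsim import discretize_lag_distribution

    sub_lags = discretize_lag_distribution(lag_distribution.lags, n_subpops)
    rng = np.random.default_rng(seed)
    t_x = doubling_glucose * math.log2(od_exhaust / od_initial)
    t_regrow = doubling_lactose * math.log2(od_capacity / od_exhaust)
    t_end = t_x + float(np.max(sub_lags)) + t_regrow + 120.0
    times = sampling_interval * np.arange(int(t_end / sampling_interval) + 1)

    def od_curve(lags: np.ndarray) -> np.ndarray:
        glucose = od_initial * 2.0 ** (times / doubling_glucose)
        total = np.minimum(glucose, od_exhaust) * (times <= t_x)
        post = np.zeros_like(times)
        for lag in lags:
            post += (od_exhaust / len(lags)) * 2.0 ** (
                np.clip(times - t_x - lag, 0.0, None) / doubling_lactose)
        out = np.where(times <= t_x, np.minimum(glucose, od_exhaust), post)
        return np.minimum(out, od_capacity)

    def make_set(lags: np.ndarray, prefix: str, iptg: bool) -> list[PlateCurve]:
        curves = []
        od = od_curve(lags)
        for r in range(n_replicates):
            noisy = baseline + od * (1.0 + noise_cv * rng.standard_normal(len(od)))
            curves.append(PlateCurve(
                well_id=f"{prefix}{r+1}",
                times=times.copy(), absorbance=noisy,
                strain="sim", condition="glucose+lactose",
                iptg_control=iptg, replicate=str(r + 1)))
        return curves

    test = make_set(sub_lags, "D", iptg=False)
    control = make_set(np.zeros_like(sub_lags), "C", iptg=True)
    return test, control


def generate_abundance_table(n_systems: int, n_conditions: int,
                             mean_log_abundance, seed: int = 0,
                             sigma_log: float = 1.5,
                             threshold_copies: float = 3.0):
    """Simulate a per-system protein abundance table across conditions.

    Each system contributes a sensor-kinase row and a response-regulator
    (transcription factor) row; condition means are log-normal around each
    system's ``mean_log_abundance`` (natural log of copies/cell) with
    log-SD ``sigma_log``.

    Returns ``(table, truth)``: a long-format DataFrame with columns
    ``protein, system, role, condition, mean_copies`` and a ground-truth
    per-system count of conditions whose kinase mean is at or below
    ``threshold_copies`` (computed from the generated values, so downstream
    recovery can be checked exactly).
    """
    if n_systems < 1 or n_conditions < 1:
        raise ValueError("counts must be >= 1")
    mu = np.broadcast_to(np.asarray(mean_log_abundance, dtype=float),
                         (n_systems,)).copy()
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for i in range(n_systems):
        system = f"TCS{i:02d}"
        kin = np.exp(mu[i] + sigma_log * rng.standard_normal(n_conditions))
        tf = np.exp(mu[i] + sigma_log * rng.standard_normal(n_conditions))
        for j in range(n_conditions):
            rows.append({"protein": f"{system}_kinase", "system": system,
                         "role": "kinase", "condition": f"cond{j:02d}",
                         "mean_copies": kin[j]})
            rows.append({"protein": f"{system}_tf", "system": system,
                         "role": "transcription_factor",
                         "condition": f"cond{j:02d}", "mean_copies": tf[j]})
        truth_rows.append({"system": system,
                           "n_sensorless_conditions":
                               int(np.sum(kin <= threshold_copies))})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
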