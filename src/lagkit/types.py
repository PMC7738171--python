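"""Core data containers shared across the lag-analysis pipeline.

Times are minutes throughout, cell lengths are in arbitrary (microscope)
length units, and fluorescence is expressed in LacZ-GFP molecule
equivalents (it may be negative after background subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CellTrace",
    "TraceSet",
    "SummedSeries",
    "GrowthLagFit",
    "LagRecord",
    "LagDistribution",
    "PlateCurve",
    "GrowthCurve",
    "InheritanceEstimate",
    "FlcsMeasurement",
]


@dataclass
class CellTrace:
    """One cell's time series from birth (or observation start) to division.

    A lineage is a set of traces linked by ``parent_id``; ``division_flag``
    is True at the last timepoint of a trace that ends in division, and the
    two daughter traces start at the *next* sampling point (so summing the
    active cells at any time never double-counts).
    """

    cell_id: str
    parent_id: Optional[str]
    experiment_id: str
    condition: str
    times: np.ndarray
    lengths: np.ndarray
    fluorescence: np.ndarray
    division_flag: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.division_flag = np.asarray(self.division_flag, dtype=bool)
        n = len(self.times)
        if not (len(self.lengths) == len(self.fluorescence) == len(self.division_flag) == n):
            raise ValueError("all per-timepoint arrays must have equal length")
        if n == 0:
            raise ValueError("empty trace")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be strictly positive")

    @property
    def spacing(self) -> float:
        if len(self.times) < 2:
            return np.nan
        return float(self.times[1] - self.times[0])

    @property
    def divides(self) -> bool:
        return bool(self.division_flag[-1])


@dataclass
class SummedSeries:
    """Total length/fluorescence of a cell and its tracked descendants.

    ``lost`` is True when a descendant left the field of view before the
    end of the series (mother-machine wash-out); the series is truncated at
    the last time every branch was still tracked.
    """

    times: np.ndarray
    length: np.ndarray
    fluorescence: np.ndarray
    lost: bool


class TraceSet:
    """A collection of :class:`CellTrace` indexed by cell id, with lineage links."""

    def __init__(self, traces):
        self.traces = {t.cell_id: t for t in traces}
        if len(self.traces) != len(list(traces)):
            raise ValueError("duplicate cell ids")
        self.children: dict[str, list[str]] = {}
        for t in self.traces.values():
            if t.parent_id is not None:
                self.children.setdefault(t.parent_id, []).append(t.cell_id)
        for kids in self.children.values():
            kids.sort()
        self.t_end = max(float(t.times[-1]) for t in self.traces.values())

    def __len__(self) -> int:
        return len(self.traces)

    def __getitem__(self, cell_id: str) -> CellTrace:
        return self.traces[cell_id]

    def __iter__(self):
        return iter(self.traces.values())

    def roots(self) -> list[str]:
        return sorted(
            cid for cid, t in self.traces.items()
            if t.parent_id is None or t.parent_id not in self.traces
        )

    def cells_alive_at(self, time: float) -> list[str]:
        return sorted(
            cid for cid, t in self.traces.items()
            if t.times[0] <= time <= t.times[-1]
        )

    def summed_series(self, focal_id: str, start_time: float) -> SummedSeries:
        """Sum length and fluorescence over the focal cell and all its tracked
        descendants, from ``start_time`` onwards.

        When a tracked cell ends without division before the end of the
        experiment, its whole branch is lost and the summed series stops at
        that time (the follow-both-daughters-until-one-is-lost rule,
        generalised to deeper trees).
        """
        sums: dict[float, list[float]] = {}
        lost_at = [np.inf]

        def walk(cid: str) -> None:
            tr = self.traces[cid]
            mask = tr.times >= start_time - 1e-9
            for t, ln, fl in zip(tr.times[mask], tr.lengths[mask], tr.fluorescence[mask]):
                s = sums.setdefault(float(t), [0.0, 0.0])
                s[0] += ln
                s[1] += fl
            end = float(tr.times[-1])
            if tr.divides:
                kids = self.children.get(cid, [])
                if len(kids) != 2:
                    raise ValueError(
                        f"cell {cid} flagged as dividing but has {len(kids)} "
                        "linked daughters"
                    )
                for k in kids:
                    walk(k)
            elif end < self.t_end - 1e-9:
                # branch washed out of the channel before the experiment ended
                lost_at[0] = min(lost_at[0], end)

        walk(focal_id)
        times = np.array(sorted(sums))
        lost = np.isfinite(lost_at[0])
        if lost:
            times = times[times <= lost_at[0] + 1e-9]
        length = np.array([sums[float(t)][0] for t in times])
        fluor = np.array([sums[float(t)][1] for t in times])
        return SummedSeries(times=times, length=length, fluorescence=fluor, lost=lost)


@dataclass
class GrowthLagFit:
    """Result of the profile-likelihood growth-lag fit on one log-size series."""

    tau_star: float              # growth lag, minutes
    lambda_star: float           # post-lag log-length growth rate, 1/min
    L0_star: float               # log-size at growth arrest
    sigma2_star: float           # measurement-noise variance of log-size
    tau_grid: np.ndarray
    loglik_profile: np.ndarray
    n_points: int                # T, number of log-size observations


@dataclass
class LagRecord:
    """Per-cell induction and growth lags with explicit censoring statuses."""

    cell_id: str
    condition: str = ""
    induction_lag: Optional[float] = None
    induction_status: str = "measured"   # measured | washed_out | non_induced
    growth_lag: Optional[float] = None
    growth_status: str = "measured"      # measured | washed_out | non_resumed
    classification: Optional[str] = None  # short | long, at a stated threshold

    def __post_init__(self) -> None:
        if self.induction_lag is not None and self.induction_lag < 0:
            raise ValueError("induction lag must be >= 0")
        if self.growth_lag is not None and self.growth_lag < 0:
            raise ValueError("growth lag must be >= 0")


@dataclass
class LagDistribution:
    """A set of measured single-cell lags with a short/long threshold."""

    lags: np.ndarray
    threshold: float = 50.0
    replicates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        if self.lags.size == 0:
            raise ValueError("empty lag distribution")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates)
            if len(self.replicates) != len(self.lags):
                raise ValueError("replicate labels must match lags")

    @property
    def fraction_short(self) -> float:
        return float(np.mean(self.lags < self.threshold))


@dataclass
class PlateCurve:
    """One plate-reader well: absorbance vs time plus condition metadata."""

    well_id: str
    times: np.ndarray
    absorbance: np.ndarray
    strain: str = ""
    condition: str = ""
    iptg_control: bool = False
    replicate: str = ""
    background: Optional[float] = None
    aligned: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(self.times) != len(self.absorbance):
            raise ValueError("times and absorbance must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def od(self) -> np.ndarray:
        if self.background is None:
            raise ValueError("background not estimated yet")
        return self.absorbance - self.background


@dataclass
class GrowthCurve:
    """A simulated population size curve."""

    times: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if len(self.times) != len(self.size):
            raise ValueError("times and size must have equal length")


@dataclass
class InheritanceEstimate:
    """Dilution estimate of reporter molecules inherited from an induced ancestor."""

    cell_id: str
    Lm: float      # ancestor's maximum LacZ-GFP during the first exposure
    nd: int        # divisions since that maximum
    inherited: float = field(init=False)

    def __post_init__(self) -> None:
        if self.nd < 0:
            raise ValueError("division count must be >= 0")
        self.inherited = self.Lm / 2.0 ** self.nd


@dataclass
class FlcsMeasurement:
    """Fitted FLCS parameters for one cell (inputs to the GFP-positive call)."""

    cpm: float                # photon counts per molecule
    cpm_cohort_median: float
    diffusion_time: float     # ms
    n_particles: float        # fitted particle number N
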