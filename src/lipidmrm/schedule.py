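"""Retention-time-window and dwell-time scheduling under a cycle budget.

A triple-quadrupole cycles through the transitions whose retention-time
windows contain the current chromatographic time. Each monitored transition
costs its dwell time plus a fixed per-transition overhead (quadrupole
settling + inter-MRM pause). The scheduler's job is to

* give every transition its own window -- wider for analytes with larger
  run-to-run retention drift or broader peaks (variable RTW), and
* split the fixed target scan time among concurrent transitions according
  to relative dwell weights -- more dwell for low-abundance analytes so
  their shot-noise-limited S/N improves (relative DTW).

When the per-transition overhead alone exceeds the target scan time, every
member falls to the minimum dwell and the cycle is flagged over budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .library import RUN_LENGTH_MIN, TransitionLibrary

__all__ = [
    "PeakStats",
    "CycleBudget",
    "WindowPolicy",
    "DwellPolicy",
    "AcquisitionSchedule",
    "assign_rt_windows",
    "assign_dwell_weights",
    "allocate_dwell",
    "concurrency_profile",
    "cycle_time_at",
    "predict_points_per_peak",
    "make_schedule",
]


@dataclass(frozen=True)
class PeakStats:
    """Empirical peak statistics for one transition (from pilot runs)."""

    transition_id: str
    mean_rt: float  # minutes
    rt_sd: float  # run-to-run retention SD, minutes
    base_halfwidth: float  # half of the peak base width, minutes
    abundance: float | None = None  # area units; None when unknown

    def __post_init__(self) -> None:
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be >= 0")
        if self.base_halfwidth <= 0:
            raise ValueError("base_halfwidth must be > 0")
        if self.abundance is not None and self.abundance <= 0:
            raise ValueError("abundance must be > 0 or None")


@dataclass(frozen=True)
class CycleBudget:
    """Instrument cycle parameters (times in ms unless noted)."""

    target_scan_time_ms: float = 500.0  # 0.5 s target scan time
    settling_time_ms: float = 5.0
    pause_time_ms: float = 5.007  # inter-MRM pause
    min_dwell_ms: float = 1.0

    def __post_init__(self) -> None:
        if min(self.target_scan_time_ms, self.settling_time_ms,
               self.pause_time_ms) <= 0:
            raise ValueError("cycle parameters must be positive")
        if self.min_dwell_ms < 1.0:
            raise ValueError("min_dwell must be >= 1 ms")

    @property
    def overhead_per_transition_ms(self) -> float:
        return self.settling_time_ms + self.pause_time_ms


@dataclass(frozen=True)
class WindowPolicy:
    """halfwidth = clamp(max(h_min, 3*rt_sd + base_halfwidth), <= h_max)."""

    h_min: float = 0.15  # minutes
    h_max: float = 1.0
    sd_multiplier: float = 3.0


@dataclass(frozen=True)
class DwellPolicy:
    """weight = clamp(sqrt(median_abundance / abundance), 1, w_max)."""

    w_max: float = 10.0


@dataclass
class AcquisitionSchedule:
    """Per-transition monitoring windows and dwell weights.

    ``mode`` is one of ``unscheduled`` (all windows span the run),
    ``scheduled-fixed`` (constant halfwidth) or ``scheduled-variable``.
    """

    ids: list[str]
    window_start: np.ndarray  # minutes
    window_end: np.ndarray
    dwell_weight: np.ndarray
    mode: str = "scheduled-variable"
    ion_mode: np.ndarray | None = None  # per-transition polarity, optional
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.window_start = np.asarray(self.window_start, dtype=float)
        self.window_end = np.asarray(self.window_end, dtype=float)
        self.dwell_weight = np.asarray(self.dwell_weight, dtype=float)
        if self.ion_mode is not None:
            self.ion_mode = np.asarray(self.ion_mode)
        if not (len(self.ids) == self.window_start.size == self.window_end.size
                == self.dwell_weight.size):
            raise ValueError("schedule arrays must share one length")
        if np.any(self.window_start >= self.window_end):
            raise ValueError("every window must satisfy start < end")
        if np.any(self.dwell_weight < 1.0):
            raise ValueError("dwell weights must be >= 1")
        if self.mode == "unscheduled" and (
            np.any(self.window_start != 0.0)
            or np.any(self.window_end != RUN_LENGTH_MIN)
        ):
            raise ValueError("unscheduled mode requires full-run windows")
        self._index = {tid: i for i, tid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, transition_id: str) -> int:
        return self._index[transition_id]

    def active_mask(self, t: float) -> np.ndarray:
        """Half-open window membership [start, end) at time ``t``."""
        return (self.window_start <= t) & (t < self.window_end)


def assign_rt_windows(
    stats: list[PeakStats], policy: WindowPolicy | None = None
) -> dict[str, tuple[float, float]]:
    """Variable retention-time windows centred on each mean RT.

    Wider windows go to transitions with larger run-to-run RT variation or
    broader peaks; the halfwidth is floored at ``h_min`` and capped at
    ``h_max``, and windows are clipped to the run span.
    """
    policy = policy or WindowPolicy()
    out = {}
    for s in stats:
        hw = max(policy.h_min, policy.sd_multiplier * s.rt_sd + s.base_halfwidth)
        hw = min(hw, policy.h_max)
        lo = max(0.0, s.mean_rt - hw)
        hi = min(RUN_LENGTH_MIN, s.mean_rt + hw)
        out[s.transition_id] = (lo, hi)
    return out


def assign_dwell_weights(
    stats: list[PeakStats], policy: DwellPolicy | None = None
) -> dict[str, float]:
    """Relative dwell weights, larger for less abundant analytes.

    The weight is sqrt(median abundance / abundance) clamped to [1, w_max]
    and rounded to 2 decimals; unknown abundance defaults to weight 1.
    """
    policy = policy or DwellPolicy()
    known = [s.abundance for s in stats if s.abundance is not None]
    median = float(np.median(known)) if known else None
    out = {}
    for s in stats:
        if s.abundance is None or median is None:
            out[s.transition_id] = 1.0
        else:
            w = np.sqrt(median / s.abundance)
            out[s.transition_id] = round(float(np.clip(w, 1.0, policy.w_max)), 2)
    return out


def allocate_dwell(
    weights: np.ndarray | list[float], budget: CycleBudget
) -> tuple[np.ndarray, float, bool]:
    """Split the cycle's available dwell time among concurrent transitions.

    Returns ``(dwell_ms, cycle_time_ms, over_budget)``. Dwell is shared
    proportionally to weight, with members floored at the minimum dwell and
    the excess redistributed proportionally among the rest. When overhead
    plus minimum dwells already exceeds the target scan time, every member
    gets the minimum dwell and the actual cycle time grows beyond target.

    Conservation holds exactly: sum(dwell) + n * overhead = cycle time.
    """
    w = np.asarray(weights, dtype=float)
    n = w.size
    if n == 0:
        raise ValueError("a cycle needs at least one member")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    overhead = n * budget.overhead_per_transition_ms
    available = budget.target_scan_time_ms - overhead
    m = budget.min_dwell_ms
    if available < n * m:
        dwell = np.full(n, m)
        return dwell, overhead + n * m, True
    # proportional allocation with min-dwell floor; excess re-distributed
    # proportionally to the remaining weights (deterministic water-filling)
    dwell = np.empty(n)
    free = np.ones(n, dtype=bool)
    remaining = available
    while True:
        share = remaining * w[free] / w[free].sum()
        low = share < m
        if not low.any():
            dwell[free] = share
            break
        idx = np.flatnonzero(free)[low]
        dwell[idx] = m
        free[idx] = False
        remaining -= m * idx.size
        if not free.any():
            break
    return dwell, budget.target_scan_time_ms, False


def concurrency_profile(
    schedule: AcquisitionSchedule, time_grid: np.ndarray | list[float]
) -> np.ndarray:
    """Number of active transitions at each grid time (half-open windows)."""
    t = np.asarray(time_grid, dtype=float)
    starts = schedule.window_start[:, None]
    ends = schedule.window_end[:, None]
    return ((starts <= t) & (t < ends)).sum(axis=0)


def cycle_time_at(
    schedule: AcquisitionSchedule,
    t: float,
    budget: CycleBudget,
    member_mask: np.ndarray | None = None,
) -> float:
    """Actual cycle time (ms) for the cycle composition active at ``t``.

    ``member_mask`` restricts the composition (e.g. to one polarity when
    positive- and negative-mode transitions cycle independently).
    """
    mask = schedule.active_mask(t)
    if member_mask is not None:
        mask = mask & member_mask
    if not mask.any():
        return budget.target_scan_time_ms
    _, cycle, _ = allocate_dwell(schedule.dwell_weight[mask], budget)
    return cycle


def predict_points_per_peak(
    schedule: AcquisitionSchedule,
    stats: list[PeakStats],
    budget: CycleBudget,
    grid_step_min: float = 0.01,
) -> dict[str, float]:
    """Expected chromatographic points per peak for every transition.

    points = (peak base width in seconds, restricted to the part covered by
    the transition's window) x (mean sampling rate over that span); the
    sampling rate at an instant is the reciprocal of the cycle time of the
    composition active there (the mean cycle time per acquired sample, i.e.
    the harmonic mean over the span). When the schedule carries per-
    transition polarities, only same-polarity transitions contribute to the
    cycle composition, matching the independent per-mode duty cycles.
    Transitions whose windows miss the peak entirely report 0 points.
    """
    out: dict[str, float] = {}
    for s in stats:
        i = schedule.index_of(s.transition_id)
        member_mask = None
        if schedule.ion_mode is not None:
            member_mask = schedule.ion_mode == schedule.ion_mode[i]
        lo = max(s.mean_rt - s.base_halfwidth, schedule.window_start[i], 0.0)
        hi = min(s.mean_rt + s.base_halfwidth, schedule.window_end[i], RUN_LENGTH_MIN)
        if hi <= lo:
            out[s.transition_id] = 0.0
            continue
        grid = np.arange(lo, hi, grid_step_min) + grid_step_min / 2
        if grid.size == 0:
            grid = np.array([(lo + hi) / 2])
        rates = np.array([
            1000.0 / cycle_time_at(schedule, t, budget, member_mask)
            for t in grid
        ])  # samples per second
        out[s.transition_id] = (hi - lo) * 60.0 * rates.mean()
    return out


def make_schedule(
    library: TransitionLibrary,
    stats: list[PeakStats] | None = None,
    mode: str = "scheduled-variable",
    fixed_halfwidth: float = 0.5,
    window_policy: WindowPolicy | None = None,
    dwell_policy: DwellPolicy | None = None,
) -> AcquisitionSchedule:
    """Derive a schedule for a library in one of the three acquisition modes.

    ``unscheduled`` monitors everything over the whole run at equal weight
    (classic MRM); ``scheduled-fixed`` centres a constant-halfwidth window
    on each expected RT (sMRM); ``scheduled-variable`` applies the variable
    RTW and relative DTW policies to the supplied peak statistics.
    """
    trans = library.all_transitions
    ids = [tr.id for tr in trans]
    modes = np.array([tr.ion_mode for tr in trans])
    if mode == "unscheduled":
        n = len(ids)
        return AcquisitionSchedule(
            ids, np.zeros(n), np.full(n, RUN_LENGTH_MIN), np.ones(n), mode, modes
        )
    if mode == "scheduled-fixed":
        start = np.array([max(0.0, tr.expected_rt - fixed_halfwidth) for tr in trans])
        end = np.array([min(RUN_LENGTH_MIN, tr.expected_rt + fixed_halfwidth)
                        for tr in trans])
        return AcquisitionSchedule(ids, start, end, np.ones(len(ids)), mode, modes)
    if mode != "scheduled-variable":
        raise ValueError(f"unknown schedule mode {mode!r}")
    if stats is None:
        raise ValueError("scheduled-variable mode needs peak statistics")
    by_id = {s.transition_id: s for s in stats}
    missing = [tid for tid in ids if tid not in by_id]
    if missing:
        raise ValueError(f"missing peak stats for {missing[:3]}...")
    ordered = [by_id[tid] for tid in ids]
    windows = assign_rt_windows(ordered, window_policy)
    weights = assign_dwell_weights(ordered, dwell_policy)
    start = np.array([windows[tid][0] for tid in ids])
    end = np.array([windows[tid][1] for tid in ids])
    w = np.array([weights[tid] for tid in ids])
    return AcquisitionSchedule(ids, start, end, w, mode, modes)
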