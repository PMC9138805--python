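"""Synthetic LC-MRM ground truth and cycle-by-cycle acquisition simulation.

The generator emulates plasma-like runs: Gaussian elution peaks with
class-clustered retention times inherited from the library's RT model,
peak base widths of 0.05-0.3 min, run-to-run retention jitter, and true
areas spanning five orders of magnitude. Acquisition advances one cycle at
a time; every transition whose retention window contains the cycle start is
sampled once per cycle for its allocated dwell time. Observed counts are
Poisson with mean (peak intensity + baseline) x dwell, and each sample is
reported normalised to counts per second, so longer dwells do not bias the
area but do shrink its shot noise like 1/sqrt(dwell).

Positive- and negative-mode transitions are monitored as two independent
schedules sharing the chromatographic clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .library import RUN_LENGTH_MIN, TransitionLibrary
from .schedule import (
    AcquisitionSchedule,
    CycleBudget,
    DwellPolicy,
    PeakStats,
    WindowPolicy,
    allocate_dwell,
    make_schedule,
    predict_points_per_peak,
)

__all__ = [
    "GroundTruthParams",
    "GroundTruthRun",
    "ChromatogramTrace",
    "PeakMeasurement",
    "generate_ground_truth_run",
    "peak_stats_from_run",
    "simulate_acquisition",
    "integrate_peaks",
    "detectability_filter",
    "compare_modes",
    "ComparisonReport",
]


@dataclass(frozen=True)
class GroundTruthParams:
    """Distributional parameters of the synthetic plasma-like fixture."""

    peak_base_width_min: float = 0.05  # minutes, 4-sigma base width
    peak_base_width_max: float = 0.30
    abundance_decades: float = 5.0
    abundance_floor: float = 1.0e3  # counts*s
    baseline_cps: float = 30.0
    rt_jitter_sd_min: float = 0.005  # minutes, per-transition run-to-run SD
    rt_jitter_sd_max: float = 0.04
    run_length_min: float = RUN_LENGTH_MIN


@dataclass
class GroundTruthRun:
    """One realized run: per-transition elution truth plus run-level seed."""

    ids: list[str]
    ion_mode: np.ndarray  # "positive"/"negative" per transition
    expected_rt: np.ndarray  # minutes (library values)
    true_rt: np.ndarray  # minutes, after run-to-run jitter
    peak_sigma: np.ndarray  # minutes
    true_area: np.ndarray  # counts*s
    baseline_cps: np.ndarray
    rt_sd: np.ndarray  # per-transition run-to-run RT SD, minutes
    seed: int
    run_length_min: float = RUN_LENGTH_MIN


@dataclass
class ChromatogramTrace:
    """Sampled (time, counts-per-second) series for one transition."""

    transition_id: str
    times: np.ndarray  # minutes, strictly increasing
    signal: np.ndarray  # counts per second, >= 0
    dwell_s: np.ndarray  # dwell used at each sample, seconds


@dataclass(frozen=True)
class PeakMeasurement:
    """Integrated peak for one transition in one replicate."""

    transition_id: str
    area: float  # counts*s
    n_points: int
    apex_time: float  # minutes
    snr: float
    missing: bool = False


def _truth_properties(
    library: TransitionLibrary, params: GroundTruthParams, seed: int
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-transition stable properties, deterministic in (library, seed)."""
    rng = np.random.default_rng(seed)
    trans = library.all_transitions
    n = len(trans)
    ids = [tr.id for tr in trans]
    modes = np.array([tr.ion_mode for tr in trans])
    rts = np.array([tr.expected_rt for tr in trans])
    sigma = rng.uniform(params.peak_base_width_min, params.peak_base_width_max, n) / 4.0
    log_area = rng.uniform(0.0, params.abundance_decades, n)
    area = params.abundance_floor * 10.0 ** log_area
    rt_sd = rng.uniform(params.rt_jitter_sd_min, params.rt_jitter_sd_max, n)
    return ids, modes, rts, sigma, area, rt_sd


def generate_ground_truth_run(
    library: TransitionLibrary,
    params: GroundTruthParams | None = None,
    seed: int = 0,
    jitter_seed: int | None = None,
) -> GroundTruthRun:
    """Draw a synthetic ground-truth run for every library transition.

    ``seed`` fixes the per-transition sample properties (peak width, true
    area, retention drift scale); ``jitter_seed`` (default: ``seed``) fixes
    the replicate-specific retention jitter, so technical replicates of the
    same sample share ``seed`` and vary ``jitter_seed``. The call is fully
    deterministic in its seeds.
    """
    params = params or GroundTruthParams()
    ids, modes, rts, sigma, area, rt_sd = _truth_properties(library, params, seed)
    jrng = np.random.default_rng(seed if jitter_seed is None else jitter_seed)
    true_rt = rts + jrng.normal(0.0, 1.0, len(ids)) * rt_sd
    true_rt = np.clip(true_rt, 0.0, params.run_length_min)
    return GroundTruthRun(
        ids=ids,
        ion_mode=modes,
        expected_rt=rts,
        true_rt=true_rt,
        peak_sigma=sigma,
        true_area=area,
        baseline_cps=np.full(len(ids), params.baseline_cps),
        rt_sd=rt_sd,
        seed=seed,
        run_length_min=params.run_length_min,
    )


def peak_stats_from_run(run: GroundTruthRun) -> list[PeakStats]:
    """Peak statistics (as a pilot study would estimate them) from truth."""
    return [
        PeakStats(
            transition_id=tid,
            mean_rt=float(run.expected_rt[i]),
            rt_sd=float(run.rt_sd[i]),
            base_halfwidth=float(2.0 * run.peak_sigma[i]),
            abundance=float(run.true_area[i]),
        )
        for i, tid in enumerate(run.ids)
    ]


def simulate_acquisition(
    run: GroundTruthRun,
    schedule: AcquisitionSchedule,
    budget: CycleBudget | None = None,
    seed: int = 0,
    noise: bool = True,
) -> dict[str, ChromatogramTrace]:
    """Cycle-by-cycle acquisition of a run under a schedule.

    Returns one trace per transition (empty traces for transitions whose
    windows never fire). With ``noise=False`` the Poisson draw is replaced
    by its expectation, which makes area recovery exact up to quadrature.
    """
    budget = budget or CycleBudget()
    if set(run.ids) - set(schedule.ids):
        raise ValueError("schedule does not cover the run's transitions")
    rng = np.random.default_rng(seed)
    sched_idx = np.array([schedule.index_of(tid) for tid in run.ids])
    starts = schedule.window_start[sched_idx]
    ends = schedule.window_end[sched_idx]
    weights = schedule.dwell_weight[sched_idx]

    rec_idx: list[np.ndarray] = []
    rec_t: list[np.ndarray] = []
    rec_sig: list[np.ndarray] = []
    rec_dwell: list[np.ndarray] = []

    for mode in ("positive", "negative"):
        group = np.flatnonzero(run.ion_mode == mode)
        if group.size == 0:
            continue
        g_start, g_end = starts[group], ends[group]
        g_w = weights[group]
        g_rt = run.true_rt[group]
        g_sig = run.peak_sigma[group]
        g_amp = run.true_area[group] / (g_sig * 60.0 * np.sqrt(2 * np.pi))
        g_base = run.baseline_cps[group]
        t = 0.0
        while t < run.run_length_min:
            active = (g_start <= t) & (t < g_end)
            if not active.any():
                upcoming = g_start[g_start > t]
                if upcoming.size == 0:
                    break
                t = float(upcoming.min())
                continue
            dwell_ms, cycle_ms, _ = allocate_dwell(g_w[active], budget)
            dwell_s = dwell_ms / 1000.0
            # peak intensity in counts/s at the cycle start
            z = (t - g_rt[active]) / g_sig[active]
            intensity = g_amp[active] * np.exp(-0.5 * z * z)
            expected = (intensity + g_base[active]) * dwell_s
            observed = rng.poisson(expected).astype(float) if noise else expected
            rec_idx.append(group[active])
            rec_t.append(np.full(active.sum(), t))
            rec_sig.append(observed / dwell_s)
            rec_dwell.append(dwell_s)
            t += cycle_ms / 60000.0

    traces: dict[str, ChromatogramTrace] = {
        tid: ChromatogramTrace(tid, np.empty(0), np.empty(0), np.empty(0))
        for tid in run.ids
    }
    if not rec_idx:
        return traces
    idx = np.concatenate(rec_idx)
    tt = np.concatenate(rec_t)
    sig = np.concatenate(rec_sig)
    dw = np.concatenate(rec_dwell)
    order = np.lexsort((tt, idx))
    idx, tt, sig, dw = idx[order], tt[order], sig[order], dw[order]
    bounds = np.flatnonzero(np.diff(idx)) + 1
    for chunk_i, chunk_t, chunk_s, chunk_d in zip(
        np.split(idx, bounds), np.split(tt, bounds),
        np.split(sig, bounds), np.split(dw, bounds),
    ):
        tid = run.ids[chunk_i[0]]
        traces[tid] = ChromatogramTrace(tid, chunk_t, chunk_s, chunk_d)
    return traces


def integrate_peaks(
    trace: ChromatogramTrace, min_samples: int = 3
) -> PeakMeasurement:
    """Baseline-subtracted trapezoidal peak area from a sampled trace.

    The baseline is the median of the lowest quartile of samples, the noise
    its SD; the peak region is the contiguous block of samples above
    baseline + 3 x noise around the maximum. Traces with fewer than
    ``min_samples`` samples, or with no sample above the threshold, come
    back flagged missing.
    """
    n = trace.times.size
    if n < min_samples:
        return PeakMeasurement(trace.transition_id, 0.0, 0, np.nan, 0.0, True)
    sorted_sig = np.sort(trace.signal)
    quart = sorted_sig[: max(1, n // 4)]
    base = float(np.median(quart))
    noise = float(np.std(quart, ddof=1)) if quart.size > 1 else 0.0
    threshold = base + 3.0 * noise
    imax = int(np.argmax(trace.signal))
    if trace.signal[imax] <= threshold:
        return PeakMeasurement(trace.transition_id, 0.0, 0, np.nan, 0.0, True)
    above = trace.signal > threshold
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < n - 1 and above[hi + 1]:
        hi += 1
    seg = slice(lo, hi + 1)
    area = float(
        np.trapezoid(trace.signal[seg] - base, trace.times[seg] * 60.0)
    )
    snr = (float(trace.signal[imax]) - base) / noise if noise > 0 else np.inf
    return PeakMeasurement(
        trace.transition_id,
        max(area, 0.0),
        hi - lo + 1,
        float(trace.times[imax]),
        snr,
        False,
    )


def detectability_filter(
    measurements: dict[str, list[PeakMeasurement]],
    min_points: int = 10,
    max_cv_percent: float = 30.0,
) -> set[str]:
    """Transitions detected across technical replicates.

    A transition counts as detected when it is present (not missing) in all
    replicates, every replicate has at least ``min_points`` points across
    the peak, and the replicate area CV is below ``max_cv_percent``.
    """
    detected = set()
    for tid, reps in measurements.items():
        if len(reps) < 2:
            raise ValueError("detectability needs >= 2 replicates")
        if any(m is None or m.missing for m in reps):
            continue
        if any(m.n_points < min_points for m in reps):
            continue
        areas = np.array([m.area for m in reps])
        if areas.mean() <= 0:
            continue
        cv = 100.0 * areas.std(ddof=1) / areas.mean()
        if cv < max_cv_percent:
            detected.add(tid)
    return detected


@dataclass
class ComparisonReport:
    """Outcome of the three-mode acquisition comparison."""

    modes: tuple[str, ...]
    detected: dict[str, set[str]]
    mean_area: dict[str, dict[str, float]]  # mode -> id -> mean area
    points: dict[str, dict[str, float]]  # mode -> id -> mean points per peak
    predicted_points: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def detected_counts(self) -> dict[str, int]:
        return {mode: len(ids) for mode, ids in self.detected.items()}

    def area_pairs(self, mode_a: str, mode_b: str) -> list[tuple[str, float, float]]:
        """(id, area_a, area_b) for transitions detected in both modes."""
        common = self.detected[mode_a] & self.detected[mode_b]
        return [
            (tid, self.mean_area[mode_a][tid], self.mean_area[mode_b][tid])
            for tid in sorted(common)
        ]


def compare_modes(
    library: TransitionLibrary,
    params: GroundTruthParams | None = None,
    budget: CycleBudget | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    fixed_halfwidth: float = 0.5,
    window_policy: WindowPolicy | None = None,
    dwell_policy: DwellPolicy | None = None,
    noise: bool = True,
    predict_points: bool = False,
) -> ComparisonReport:
    """Simulate unscheduled MRM, fixed-window sMRM and variable-RTW/DTW
    acquisition of the same synthetic replicates and compare detection.

    The same ground-truth sample (per-transition widths, areas, drift
    scales) underlies all three modes; only the acquisition schedule
    differs. Replicates share the sample and vary the retention jitter.
    """
    params = params or GroundTruthParams()
    budget = budget or CycleBudget()
    ss = np.random.SeedSequence(seed)
    prop_seed, *rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                             for s in ss.spawn(1 + 2 * n_replicates)]
    pilot = generate_ground_truth_run(library, params, prop_seed)
    stats = peak_stats_from_run(pilot)
    schedules = {
        "mrm": make_schedule(library, mode="unscheduled"),
        "smrm": make_schedule(library, mode="scheduled-fixed",
                              fixed_halfwidth=fixed_halfwidth),
        "advanced": make_schedule(library, stats, mode="scheduled-variable",
                                  window_policy=window_policy,
                                  dwell_policy=dwell_policy),
    }
    measurements: dict[str, dict[str, list[PeakMeasurement]]] = {
        m: {tid: [] for tid in pilot.ids} for m in schedules
    }
    points: dict[str, dict[str, list[float]]] = {
        m: {tid: [] for tid in pilot.ids} for m in schedules
    }
    for rep in range(n_replicates):
        run = generate_ground_truth_run(
            library, params, prop_seed, jitter_seed=rep_seeds[rep]
        )
        for mode, sched in schedules.items():
            traces = simulate_acquisition(
                run, sched, budget, seed=rep_seeds[n_replicates + rep], noise=noise
            )
            for tid, trace in traces.items():
                meas = integrate_peaks(trace)
                measurements[mode][tid].append(meas)
                points[mode][tid].append(float(meas.n_points))
    detected = {m: detectability_filter(measurements[m]) for m in schedules}
    mean_area = {
        m: {
            tid: float(np.mean([x.area for x in reps]))
            for tid, reps in measurements[m].items()
            if not any(x.missing for x in reps)
        }
        for m in schedules
    }
    mean_points = {
        m: {tid: float(np.mean(v)) for tid, v in points[m].items()}
        for m in schedules
    }
    report = ComparisonReport(
        modes=tuple(schedules), detected=detected,
        mean_area=mean_area, points=mean_points,
    )
    if predict_points:
        for m, sched in schedules.items():
            report.predicted_points[m] = predict_points_per_peak(
                sched, stats, budget
            )
    return report
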