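"""Ground-truth generation, acquisition simulation and peak detection."""

import numpy as np
import pytest

from lipidmrm.schedule import AcquisitionSchedule, CycleBudget, make_schedule
from lipidmrm.simulate import (
    ChromatogramTrace,
    GroundTruthParams,
    GroundTruthRun,
    PeakMeasurement,
    compare_modes,
    detectability_filter,
    generate_ground_truth_run,
    integrate_peaks,
    simulate_acquisition,
)

BUDGET = CycleBudget()


class TestGroundTruth:
    def test_fixed_seed_is_deterministic(self, small_library):
        a = generate_ground_truth_run(small_library, seed=7)
        b = generate_ground_truth_run(small_library, seed=7)
        assert np.array_equal(a.true_rt, b.true_rt)
        assert np.array_equal(a.true_area, b.true_area)

    def test_zero_jitter_keeps_expected_rt(self, small_library):
        params = GroundTruthParams(rt_jitter_sd_min=0.0, rt_jitter_sd_max=0.0)
        run = generate_ground_truth_run(small_library, params, seed=3)
        assert np.allclose(run.true_rt, run.expected_rt)

    def test_abundances_span_configured_decades(self, full_library):
        params = GroundTruthParams(abundance_decades=5.0)
        run = generate_ground_truth_run(full_library, params, seed=5)
        log10 = np.log10(run.true_area / params.abundance_floor)
        span = log10.max() - log10.min()
        assert span == pytest.approx(5.0, rel=0.05)
        assert log10.min() >= 0.0

    def test_replicates_share_sample_but_jitter_differs(self, small_library):
        a = generate_ground_truth_run(small_library, seed=7, jitter_seed=1)
        b = generate_ground_truth_run(small_library, seed=7, jitter_seed=2)
        assert np.array_equal(a.true_area, b.true_area)
        assert not np.array_equal(a.true_rt, b.true_rt)


class TestSimulateAcquisition:
    def test_traces_stay_inside_windows_and_increase(self, small_library):
        run = generate_ground_truth_run(small_library, seed=2)
        sched = make_schedule(small_library, mode="scheduled-fixed",
                              fixed_halfwidth=0.4)
        traces = simulate_acquisition(run, sched, BUDGET, seed=0)
        checked = 0
        for tid, tr in traces.items():
            if tr.times.size < 2:
                continue
            j = sched.index_of(tid)
            assert np.all(np.diff(tr.times) > 0)
            assert tr.times.min() >= sched.window_start[j]
            assert tr.times.max() < sched.window_end[j]
            assert np.all(tr.signal >= 0)
            checked += 1
        assert checked > 10

    def test_noiseless_recovery_on_generous_windows(self, small_library):
        """With no baseline and no noise, trapezoid areas match truth <1%."""
        params = GroundTruthParams(baseline_cps=0.0, rt_jitter_sd_min=0.0,
                                   rt_jitter_sd_max=0.0)
        run = generate_ground_truth_run(small_library, params, seed=4)
        sched = make_schedule(small_library, mode="scheduled-fixed",
                              fixed_halfwidth=0.7)
        traces = simulate_acquisition(run, sched, BUDGET, seed=0, noise=False)
        idx = {tid: i for i, tid in enumerate(run.ids)}
        n_checked = 0
        for tid, tr in traces.items():
            m = integrate_peaks(tr)
            if m.missing or m.n_points < 10:
                continue
            i = idx[tid]
            # only peaks sampled finely relative to their width integrate
            # accurately (trapezoid quadrature)
            in_peak = np.abs(tr.times - run.true_rt[i]) <= 3 * run.peak_sigma[i]
            if in_peak.sum() < 2:
                continue
            if np.diff(tr.times[in_peak]).max() > run.peak_sigma[i]:
                continue
            assert m.area == pytest.approx(run.true_area[i], rel=0.01)
            n_checked += 1
        assert n_checked >= 20

    def test_doubling_dwell_improves_area_cv_like_sqrt2(self):
        """Relative dwell weighting buys shot-noise S/N, not area bias."""
        n = 40
        ids = [f"T{i}" for i in range(n)]
        run = GroundTruthRun(
            ids=ids, ion_mode=np.array(["positive"] * n),
            expected_rt=np.full(n, 5.0), true_rt=np.full(n, 5.0),
            peak_sigma=np.full(n, 0.05),
            true_area=np.r_[5e4, np.full(n - 1, 1e6)],
            baseline_cps=np.full(n, 50.0), rt_sd=np.zeros(n), seed=0,
        )

        def area_cv(weight):
            w = np.ones(n)
            w[0] = weight
            sched = AcquisitionSchedule(ids, np.full(n, 4.4), np.full(n, 5.6), w)
            areas = np.array([
                integrate_peaks(
                    simulate_acquisition(run, sched, BUDGET, seed=3000 + r)["T0"]
                ).area
                for r in range(200)
            ])
            return areas.std(ddof=1) / areas.mean()

        ratio = area_cv(1.0) / area_cv(2.0)
        assert 1.2 < ratio < 1.7  # ~sqrt(2) from ~doubled dwell

    def test_area_cv_decreases_with_true_area(self):
        """Shot-noise model: darker peaks are noisier in replicate area."""
        ids = ["lo", "mid", "hi"]
        run = GroundTruthRun(
            ids=ids, ion_mode=np.array(["positive"] * 3),
            expected_rt=np.full(3, 5.0), true_rt=np.full(3, 5.0),
            peak_sigma=np.full(3, 0.05),
            true_area=np.array([2e3, 2e4, 2e5]),
            baseline_cps=np.full(3, 30.0), rt_sd=np.zeros(3), seed=0,
        )
        sched = AcquisitionSchedule(ids, np.full(3, 4.4), np.full(3, 5.6),
                                    np.ones(3))
        areas = {tid: [] for tid in ids}
        for r in range(120):
            traces = simulate_acquisition(run, sched, BUDGET, seed=500 + r)
            for tid in ids:
                areas[tid].append(integrate_peaks(traces[tid]).area)
        cvs = {
            tid: np.std(v, ddof=1) / np.mean(v) for tid, v in areas.items()
        }
        assert cvs["lo"] > cvs["mid"] > cvs["hi"]


class TestIntegratePeaks:
    def test_dense_noiseless_gaussian_within_one_percent(self):
        t = np.arange(0, 4, 0.005)
        sigma, area = 0.05, 1234.0
        sig = area / (sigma * 60 * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - 2.0) / sigma) ** 2
        )
        m = integrate_peaks(ChromatogramTrace("x", t, sig, np.full(t.size, 0.01)))
        assert not m.missing
        assert m.area == pytest.approx(area, rel=0.01)
        assert m.apex_time == pytest.approx(2.0, abs=0.01)

    def test_flat_zero_trace_is_missing(self):
        t = np.arange(0, 1, 0.01)
        m = integrate_peaks(ChromatogramTrace("x", t, np.zeros(t.size),
                                              np.full(t.size, 0.01)))
        assert m.missing and m.area == 0.0

    def test_too_few_samples_flagged_missing(self):
        m = integrate_peaks(
            ChromatogramTrace("x", np.array([1.0, 1.1]), np.array([5.0, 6.0]),
                              np.array([0.01, 0.01]))
        )
        assert m.missing

    def test_random_peaks_match_dense_oracle(self, rng):
        """Trapezoid area against independent dense-grid quadrature."""
        for _ in range(50):
            sigma = rng.uniform(0.02, 0.08)
            area = 10 ** rng.uniform(3, 6)
            rt = rng.uniform(5, 6)
            t = np.arange(rt - 0.6, rt + 0.6, 0.008)
            clean = area / (sigma * 60 * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((t - rt) / sigma) ** 2
            )
            m = integrate_peaks(
                ChromatogramTrace("x", t, clean, np.full(t.size, 0.01))
            )
            dense = np.arange(rt - 0.6, rt + 0.6, 1e-4)
            oracle = np.trapezoid(
                area / (sigma * 60 * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((dense - rt) / sigma) ** 2),
                dense * 60.0,
            )
            assert m.area == pytest.approx(oracle, rel=0.05)


class TestDetectabilityFilter:
    def meas(self, points, areas):
        return [
            PeakMeasurement("t", a, npt, 10.0, 50.0, False)
            for npt, a in zip(points, areas)
        ]

    def test_good_replicates_detected(self):
        reps = self.meas([12, 11, 10, 13, 12], [100, 104, 96, 108, 92])
        assert detectability_filter({"t": reps}) == {"t"}

    def test_one_low_point_replicate_rejects(self):
        reps = self.meas([12, 11, 9, 13, 12], [100, 104, 96, 108, 92])
        assert detectability_filter({"t": reps}) == set()

    def test_high_cv_rejects(self):
        reps = self.meas([12, 11, 10, 13, 12], [100, 180, 50, 140, 60])
        areas = np.array([100, 180, 50, 140, 60])
        assert 100 * areas.std(ddof=1) / areas.mean() > 30
        assert detectability_filter({"t": reps}) == set()

    def test_missing_replicate_rejects(self):
        reps = self.meas([12, 11, 10, 13], [100, 104, 96, 108])
        reps.append(PeakMeasurement("t", 0.0, 0, np.nan, 0.0, True))
        assert detectability_filter({"t": reps}) == set()


class TestCompareModes:
    def test_easy_regime_all_modes_equivalent(self):
        """Ten well-separated abundant wide peaks: every mode detects all."""
        from lipidmrm.library import MrmTransition, TransitionLibrary
        from lipidmrm.species import LipidSpecies

        lib = TransitionLibrary()
        for i in range(10):
            lib.transitions.append(MrmTransition(
                id=f"p{i}", species=LipidSpecies("PC", 30 + i, 1),
                q1=700.0 + i, q3=280.0, ion_mode="negative",
                expected_rt=2.0 + 2.0 * i,
            ))
        params = GroundTruthParams(
            peak_base_width_min=0.25, peak_base_width_max=0.30,
            abundance_decades=1.0, abundance_floor=1e6,
            rt_jitter_sd_min=0.005, rt_jitter_sd_max=0.01,
        )
        report = compare_modes(lib, params, BUDGET, n_replicates=3, seed=9)
        assert report.detected_counts == {"mrm": 10, "smrm": 10, "advanced": 10}

    def test_mode_ordering_on_small_panel(self, small_library):
        report = compare_modes(small_library, n_replicates=3, seed=2)
        c = report.detected_counts
        assert c["advanced"] >= c["smrm"] >= c["mrm"]
        assert c["advanced"] > 0
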