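"""Synthetic EMG generator: ground-truth curves, trials, runs, gating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hreflex import (
    GatingSpec,
    RecruitmentTruth,
    SweepProtocol,
    WaveformSpec,
    generate_run,
    generate_trial,
    simulate_gating,
    true_h_amplitude,
    true_m_amplitude,
)
from hreflex.bands import H_WINDOW_MS, M_WINDOW_MS
from hreflex.simulate import draw_truth, generate_cohort


class TestTruthCurves:
    def test_m_sigmoid_midpoint_and_asymptote(self, truth):
        assert true_m_amplitude(truth.m_center, truth) == pytest.approx(truth.m_max / 2)
        far = truth.m_center + 1000.0 / truth.m_slope
        assert true_m_amplitude(far, truth) == pytest.approx(truth.m_max, abs=1e-9)

    def test_m_matches_independent_logistic_evaluation(self):
        # direct evaluation of m_max / (1 + exp(-b (s - c))) at s = 22
        t = RecruitmentTruth(m_max=4.0, m_center=20.0, m_slope=0.5)
        expected = 4.0 / (1.0 + math.exp(-0.5 * (22.0 - 20.0)))
        assert true_m_amplitude(22.0, t) == pytest.approx(expected, rel=1e-12)

    def test_m_monotone_on_fine_grid(self, truth):
        grid = np.arange(0.0, 50.0, 0.01)
        assert np.all(np.diff(true_m_amplitude(grid, truth)) >= 0)

    def test_h_negligible_far_below_threshold(self, truth):
        assert true_h_amplitude(0.0, truth) < 1e-3 * truth.h_scale

    def test_h_symmetric_truth_peaks_at_center_midpoint(self):
        t = RecruitmentTruth(h_rise_center=10.0, h_fall_center=20.0,
                             h_rise_slope=0.7, h_fall_slope=0.7)
        grid = np.arange(0.0, 40.0, 0.001)
        argmax = grid[np.argmax(true_h_amplitude(grid, t))]
        assert argmax == pytest.approx(15.0, abs=0.001)

    def test_h_grid_argmax_matches_brute_force_scan(self, truth):
        coarse = np.arange(0.0, 50.0, 0.01)
        fine = np.arange(0.0, 50.0, 0.001)
        a_coarse = coarse[np.argmax(true_h_amplitude(coarse, truth))]
        a_fine = fine[np.argmax(true_h_amplitude(fine, truth))]
        assert a_coarse == pytest.approx(a_fine, abs=0.01)

    def test_negative_intensity_rejected(self, truth):
        with pytest.raises(ValueError):
            true_m_amplitude(-1.0, truth)
        with pytest.raises(ValueError):
            true_h_amplitude(-0.5, truth)

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError):
            RecruitmentTruth(h_rise_center=25.0, h_fall_center=20.0)
        with pytest.raises(ValueError):
            RecruitmentTruth(m_slope=-0.1)
        with pytest.raises(ValueError):
            RecruitmentTruth(m_max=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_drawn_truths_are_unimodal_h_and_monotone_m(self, seed):
        t = draw_truth(np.random.default_rng(seed))
        grid = np.arange(0.0, 50.0, 0.01)
        h = true_h_amplitude(grid, t)
        ipk = int(np.argmax(h))
        assert np.all(np.diff(h[: ipk + 1]) >= -1e-12)
        assert np.all(np.diff(h[ipk:]) <= 1e-12)
        assert np.all(np.diff(true_m_amplitude(grid, t)) >= 0)


def _window_mrv(trial, fs, window):
    t_ms = (np.arange(len(trial.samples)) - trial.trigger_index) * 1000.0 / fs
    mask = (t_ms >= window[0]) & (t_ms < window[1])
    return np.abs(trial.samples[mask]).mean()


class TestGenerateTrial:
    def test_noiseless_mrv_matches_truth_in_canonical_windows(self, truth, rng):
        # isolate the template-normalization contract: no noise, no trial
        # variability, and no artifact/decay components (those are removed by
        # the measurement pipeline, not by a raw window read)
        wspec = WaveformSpec(noise_rms=0.0, trial_cv=0.0,
                             artifact_amp=0.0, decay_amp=0.0)
        for s in (10.0, 18.0, 30.0):
            trial = generate_trial(s, truth, wspec, 3200, rng)
            assert _window_mrv(trial, 3200, M_WINDOW_MS) == pytest.approx(
                true_m_amplitude(s, truth), rel=0.01, abs=1e-9)
            assert _window_mrv(trial, 3200, H_WINDOW_MS) == pytest.approx(
                true_h_amplitude(s, truth), rel=0.01, abs=1e-9)

    def test_noisy_trials_unbiased_around_clean_value(self, truth):
        # Monte Carlo: with trial_cv=0 the mean measured MRV over noisy trials
        # must sit within 3 standard errors of the clean value
        wspec = WaveformSpec(trial_cv=0.0)
        s = 20.0
        rng = np.random.default_rng(42)
        vals = [
            _window_mrv(generate_trial(s, truth, wspec, 3200, rng), 3200, H_WINDOW_MS)
            for _ in range(100)
        ]
        clean = true_h_amplitude(s, truth)
        # the noise floor adds a small positive offset to the rectified mean
        floor = 0.9 * wspec.noise_rms
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - clean) < 3 * sem + floor

    def test_same_seed_bit_identical(self, truth, noisy_wspec):
        a = generate_trial(15.0, truth, noisy_wspec, 3200, np.random.default_rng(3))
        b = generate_trial(15.0, truth, noisy_wspec, 3200, np.random.default_rng(3))
        assert np.array_equal(a.samples, b.samples)
        assert a.trigger_index == b.trigger_index

    def test_non_integer_fs_rejected(self, truth, clean_wspec, rng):
        with pytest.raises(ValueError):
            generate_trial(10.0, truth, clean_wspec, 3200.5, rng)
        with pytest.raises(ValueError):
            generate_trial(10.0, truth, clean_wspec, 300, rng)


class TestGenerateRun:
    def test_trial_counting_and_ramp_order(self, clean_wspec):
        # 11 steps of 4 trials: 10,10,10,10,11,... up to 20
        truth = RecruitmentTruth()  # plateau far above 20 mA
        proto = SweepProtocol(start_intensity=10.0, step=1.0, trials_per_step=4,
                              max_intensity=20.0)
        run = generate_run(truth, proto, clean_wspec, seed=0)
        intensities = [t.intensity for t in run.trials]
        assert len(intensities) == 44
        assert intensities[:5] == [10.0, 10.0, 10.0, 10.0, 11.0]
        assert intensities == sorted(intensities)

    def test_plateau_stop_rule_ends_ramp_before_cap(self, truth, clean_wspec):
        proto = SweepProtocol(start_intensity=6.0, step=1.0, trials_per_step=1,
                              max_intensity=50.0)
        run = generate_run(truth, proto, clean_wspec, seed=0)
        last = run.trials[-1].intensity
        assert last < 50.0
        # stop after two consecutive steps above 99% of the asymptote
        assert true_m_amplitude(last, truth) >= 0.99 * truth.m_max
        assert true_m_amplitude(last - 1.0, truth) >= 0.99 * truth.m_max

    def test_same_seed_reproducible_and_subjects_differ(self, truth, protocol, noisy_wspec):
        a = generate_run(truth, protocol, noisy_wspec, subject_id="X", seed=5)
        b = generate_run(truth, protocol, noisy_wspec, subject_id="X", seed=5)
        c = generate_run(truth, protocol, noisy_wspec, subject_id="Y", seed=5)
        assert all(np.array_equal(x.samples, y.samples)
                   for x, y in zip(a.trials, b.trials))
        assert not np.array_equal(a.trials[0].samples, c.trials[0].samples)

    def test_isi_jittered_around_one_second(self, noisy_run):
        isis = np.array([t.isi for t in noisy_run.trials])
        assert np.all((isis >= 0.9) & (isis <= 1.1))
        assert isis.std() > 0

    def test_empty_ramp_rejected(self, truth, clean_wspec):
        proto = SweepProtocol(start_intensity=30.0, step=1.0, max_intensity=20.0)
        with pytest.raises(ValueError, match="empty ramp"):
            generate_run(truth, proto, clean_wspec, seed=0)

    def test_cohort_reproducible_and_heterogeneous(self):
        runs = generate_cohort(3, master_seed=9)
        runs2 = generate_cohort(3, master_seed=9)
        assert [r.truth for r in runs] == [r.truth for r in runs2]
        assert len({r.truth.m_center for r in runs}) == 3
        # growing the cohort must not perturb existing subjects
        runs4 = generate_cohort(4, master_seed=9)
        assert runs4[0].truth == runs[0].truth
        assert np.array_equal(runs4[2].trials[0].samples, runs[2].trials[0].samples)


class TestGating:
    def test_quiet_background_permitted_after_hold(self):
        fs = 100
        gspec = GatingSpec()
        flags = simulate_gating(np.full(500, 3.0), gspec, fs)
        hold = int(gspec.hold_duration * fs)
        assert not flags[: hold - 1].any()
        assert flags[hold - 1 :].all()

    def test_loud_background_never_permitted(self):
        flags = simulate_gating(np.full(500, 25.0), GatingSpec(), 100)
        assert not flags.any()

    def test_single_sample_excursion_resets_hold_exactly(self):
        fs = 100
        gspec = GatingSpec()
        bg = np.full(600, 3.0)
        bg[300] = 30.0
        flags = simulate_gating(bg, gspec, fs)
        hold = int(gspec.hold_duration * fs)
        assert not flags[300]
        assert not flags[300 + hold - 1]
        assert flags[300 + hold]  # restored exactly one hold duration later

    def test_series_shorter_than_hold_rejected(self):
        with pytest.raises(ValueError):
            simulate_gating(np.zeros(10), GatingSpec(), 100)
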