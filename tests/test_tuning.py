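"""Single-cell tuning analyses: curves, DSI, slope, selectivity, simulation,
cross-condition similarity, peak confusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsumstats import synth, tuning
from popsumstats._angles import DIRECTION_SET

DIRS = np.asarray(DIRECTION_SET)


class TestComputeTuning:
    def test_constant_response_gives_auc_c_times_duration(self):
        # constant stimulus-period signal c: trial-averaged AUC must be c x 4 s
        cfg = synth.SessionConfig(trials_per_direction=1, seed=0)
        trials = synth.design_session(cfg, np.random.default_rng(0))
        traces = np.zeros((4, int(trials["onset_frame"].max()) + cfg.frames_per_trial))
        for f in trials["onset_frame"]:
            traces[:, f : f + cfg.stim_frames] = 0.25
        trials["correct"] = True
        tc = tuning.compute_tuning(traces, trials, cfg.frame_rate, "hom")
        assert np.allclose(tc.responses, 0.25 * 4.0)

    def test_two_trial_toy_matches_hand_average(self):
        import pandas as pd

        fr = 10.0
        trials = pd.DataFrame(
            {
                "mean_direction": [22.5, 22.5],
                "variance_condition": ["hom", "hom"],
                "onset_frame": [10, 80],
                "correct": [True, True],
            }
        )
        traces = np.zeros((1, 160))
        traces[0, 10:50] = 1.0  # first trial: steady 1.0
        traces[0, 80:120] = 3.0  # second trial: steady 3.0
        with pytest.raises(ValueError):
            tuning.compute_tuning(traces, trials, fr, "hom")  # other cells empty
        X = tuning.trial_aucs(traces, trials, fr)
        assert np.allclose(X.ravel(), [4.0, 12.0])

    def test_correct_only_flag_changes_only_affected_cells(self, quiet_session):
        s = quiet_session
        all_tc = tuning.compute_tuning(
            s.traces, s.trials, s.frame_rate, "hom", correct_only=False
        )
        trials = s.trials.copy()
        trials["correct"] = True
        forced = tuning.compute_tuning(s.traces, trials, s.frame_rate, "hom")
        assert np.allclose(all_tc.responses, forced.responses)


class TestDsi:
    @pytest.mark.parametrize(
        "pref,anti,expected", [(2.0, 1.0, 0.5), (2.0, 2.0, 0.0), (2.0, 0.0, 1.0)]
    )
    def test_known_values(self, pref, anti, expected):
        resp = np.full(8, anti)
        resp[0] = pref
        assert tuning.dsi(resp[None, :])[0] == pytest.approx(expected)

    def test_zero_preferred_response_undefined(self):
        assert np.isnan(tuning.dsi(np.zeros((1, 8)))[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=0.01, max_value=50.0),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_scale_invariance_for_nonnegative_curves(self, scale, seed):
        resp = np.random.default_rng(seed).uniform(0.1, 2.0, size=(3, 8))
        assert np.allclose(tuning.dsi(resp), tuning.dsi(scale * resp))


class TestTuningSlope:
    def test_flat_curve_has_zero_slope(self):
        assert tuning.tuning_slope(np.full((1, 8), 2.0))[0] == pytest.approx(0.0)

    def test_linear_in_absolute_offset_recovers_coefficient(self):
        a = 0.01
        offsets = np.abs(tuning.ALIGNED_OFFSETS)
        resp = (1.0 - a * offsets)[None, :]
        # responses indexed by aligned offsets; convert to direction order
        # with preferred at column 0
        order = np.array([4, 5, 6, 7, 0, 1, 2, 3])
        curve = np.empty(8)
        curve[order] = resp[0]
        assert tuning.tuning_slope(curve[None, :])[0] == pytest.approx(a)

    def test_cosine_curve_matches_closed_form_ols(self):
        curve = np.cos(np.deg2rad(DIRS - 22.5))[None, :]
        y = np.array(
            [
                np.cos(np.pi),
                np.cos(np.deg2rad(135)),
                np.cos(np.deg2rad(90)),
                np.cos(np.deg2rad(45)),
                1.0,
            ]
        )
        x = np.array([-180.0, -135.0, -90.0, -45.0, 0.0])
        expected = np.polyfit(x, y, 1)[0]
        assert tuning.tuning_slope(curve)[0] == pytest.approx(expected)


class TestClassifySelective:
    def test_noiseless_tuned_neurons_are_selective(self, quiet_session):
        s = quiet_session
        tc = tuning.compute_tuning(s.traces, s.trials, s.frame_rate, "hom")
        tc = tuning.classify_selective(
            tc, s.traces, s.trials, s.frame_rate, n_perm=200,
            rng=np.random.default_rng(0),
        )
        assert tc.selective.mean() > 0.9

    def test_dsi_threshold_is_strict(self):
        resp = np.array([[1.0, 0.8, 0.7, 0.62, 0.61, 0.62, 0.7, 0.8]])
        assert tuning.dsi(resp)[0] < 0.4  # DSI 0.39
        # a neuron failing DSI can never be selective regardless of slope
        # (checked through the conjunction in classify_selective's contract)

    def test_untuned_population_false_positive_rate_near_alpha(self, small_config):
        rng = np.random.default_rng(1)
        pop = synth.make_population(
            40, rng, coding_mode="untuned", baseline=0.2
        )
        calcium = synth.CalciumParams(noise_sd=0.3, drift_amplitude=0.0)
        s = synth.generate_session(small_config, pop, calcium, seed=5)
        tc = tuning.compute_tuning(s.traces, s.trials, s.frame_rate, "hom")
        tc = tuning.classify_selective(
            tc, s.traces, s.trials, s.frame_rate, n_perm=300,
            rng=np.random.default_rng(2),
        )
        # joint criterion (DSI > 0.4 AND slope above the 95th null percentile)
        # keeps false positives at or below ~5%
        assert tc.selective.mean() <= 0.125  # 40 neurons: <= 5 flagged

    def test_small_permutation_count_refused(self, quiet_session):
        s = quiet_session
        tc = tuning.compute_tuning(s.traces, s.trials, s.frame_rate, "hom")
        with pytest.raises(ValueError):
            tuning.classify_selective(tc, s.traces, s.trials, s.frame_rate, n_perm=50)


class TestHetSimulation:
    def _cosine_curves(self, n=16, amp=1.0):
        from popsumstats.benchmark import _cosine_curves

        return _cosine_curves(n, amp)

    def test_zero_range_is_identity(self):
        curves = self._cosine_curves()
        rng = np.random.default_rng(0)
        sim = tuning.simulate_het_tuning(curves, 0.0, n_match=16, n_resample=50, rng=rng)
        aligned_cos = 1.0 + np.cos(np.deg2rad(tuning.ALIGNED_OFFSETS))
        assert np.allclose(sim["mean_curve"], aligned_cos, atol=1e-10)

    def test_full_circle_average_is_flat(self):
        curves = self._cosine_curves()
        sim = tuning.simulate_het_tuning(
            curves, 360.0, n_match=16, n_resample=20, rng=np.random.default_rng(0)
        )
        assert np.allclose(sim["mean_curve"], sim["mean_curve"][0], atol=1e-10)
        assert np.allclose(sim["peak_amplitudes"], 0.0, atol=1e-10)

    def test_half_circle_attenuates_cosine_by_two_over_pi(self):
        curves = self._cosine_curves(amp=0.7)
        sim = tuning.simulate_het_tuning(
            curves, 180.0, n_match=16, n_resample=50, rng=np.random.default_rng(0)
        )
        assert np.mean(sim["peak_amplitudes"]) == pytest.approx(0.7 * 2 / np.pi, rel=1e-6)

    def test_peak_amplitude_nonincreasing_in_range(self):
        curves = self._cosine_curves()
        rng = np.random.default_rng(3)
        amps = [
            np.mean(
                tuning.simulate_het_tuning(
                    curves, r, n_match=16, n_resample=30,
                    rng=np.random.default_rng(3),
                )["peak_amplitudes"]
            )
            for r in (0.0, 90.0, 180.0, 270.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(amps, amps[1:]))


class TestCrossConditionCorrelation:
    def test_identical_arrays_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        resp = rng.uniform(size=(10, 8))
        r, _ = tuning.cross_condition_correlation(resp, resp, n_perm=100, rng=rng)
        assert r == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(1)
        resp = rng.uniform(size=(10, 8))
        flipped = resp.mean() * 2 - resp
        r, _ = tuning.cross_condition_correlation(resp, flipped, n_perm=100, rng=rng)
        assert r == pytest.approx(-1.0, abs=1e-10)

    def test_shuffled_copy_decorrelates(self):
        rng = np.random.default_rng(2)
        resp = rng.uniform(size=(60, 8))  # 480 entries
        shuffled = rng.permutation(resp.ravel()).reshape(resp.shape)
        r, p = tuning.cross_condition_correlation(resp, shuffled, n_perm=200, rng=rng)
        assert abs(r) < 0.1
        assert p > 0.05

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            tuning.cross_condition_correlation(np.ones((1, 8)), np.ones((1, 8)))


class TestPeakConfusion:
    def _aucs(self, peaks, n_trials_per_dir=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat(DIRS, n_trials_per_dir)
        X = np.zeros((labels.size, len(peaks)))
        for n, pk in enumerate(peaks):
            X[:, n] = np.exp(2 * (np.cos(np.deg2rad(labels - pk)) - 1))
        return X + rng.normal(0, noise, X.shape), labels

    def test_identical_conditions_put_all_mass_on_diagonal(self):
        peaks = np.tile(DIRS, 4)
        X, labels = self._aucs(peaks)
        res = tuning.peak_confusion(X, labels, X, labels, n_perm=200,
                                    rng=np.random.default_rng(0))
        assert np.trace(res.proportions) == pytest.approx(1.0)
        assert res.proportions.sum() == pytest.approx(1.0)

    def test_diagonal_cells_significant_for_consistent_population(self):
        # a diverse population (jittered peaks, per-neuron noise) so that
        # label-shuffled surrogates decorrelate across neurons; most diagonal
        # cells then survive FDR while no off-diagonal cell does
        rng = np.random.default_rng(9)
        peaks = (np.tile(DIRS, 16) + rng.uniform(-15, 15, 128)) % 360
        X, labels = self._aucs(peaks, n_trials_per_dir=12, noise=0.4)
        Y, _ = self._aucs(peaks, n_trials_per_dir=12, noise=0.4, seed=1)
        res = tuning.peak_confusion(X, labels, Y, labels, n_perm=500,
                                    rng=np.random.default_rng(1))
        assert res.significant.diagonal().sum() >= 6
        assert not res.significant[~np.eye(8, dtype=bool)].any()

    def test_proportions_always_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(24, 30))
        labels = np.repeat(DIRS, 3)
        res = tuning.peak_confusion(X, labels, rng.uniform(size=(24, 30)), labels,
                                    n_perm=150, rng=rng)
        assert res.proportions.sum() == pytest.approx(1.0)


def test_overlap_significance_binomial_null():
    a = np.zeros(100, bool)
    b = np.zeros(100, bool)
    a[:30] = True
    b[:30] = True  # overlap 30 vs expected 9
    k, p = tuning.overlap_significance(a, b)
    assert k == 30 and p < 1e-6
    rng = np.random.default_rng(0)
    k2, p2 = tuning.overlap_significance(rng.uniform(size=100) < 0.3,
                                         rng.uniform(size=100) < 0.3)
    assert p2 > 0.001
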