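"""Generator contracts: schedule balance, stimulus statistics, rate models,
calcium dynamics, and choice behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from popsumstats import synth
from popsumstats._angles import DIRECTION_SET, circmean_deg, wrap180


def _violations(trials: pd.DataFrame) -> int:
    same_dir = trials["mean_direction"].values[1:] == trials["mean_direction"].values[:-1]
    same_var = (
        trials["variance_condition"].values[1:] == trials["variance_condition"].values[:-1]
    )
    return int((same_dir & same_var).sum())


class TestDesignSession:
    def test_default_session_is_160_plus_160_in_16_types(self):
        cfg = synth.SessionConfig(seed=0)
        trials = synth.design_session(cfg, np.random.default_rng(0))
        assert len(trials) == 320
        assert (trials["variance_condition"] == "hom").sum() == 160
        assert (trials["variance_condition"] == "het").sum() == 160
        cells = trials.groupby(["mean_direction", "variance_condition"]).size()
        assert len(cells) == 16
        assert (cells == 20).all()
        assert _violations(trials) == 0

    def test_one_trial_per_type_gives_16_rows(self):
        cfg = synth.SessionConfig(trials_per_direction=1, seed=0)
        trials = synth.design_session(cfg, np.random.default_rng(0))
        assert len(trials) == 16
        assert trials.groupby(["mean_direction", "variance_condition"]).size().eq(1).all()

    def test_same_seed_reproduces_schedule(self):
        cfg = synth.SessionConfig(trials_per_direction=4, seed=0)
        a = synth.design_session(cfg, np.random.default_rng(7))
        b = synth.design_session(cfg, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            synth.SessionConfig(trials_per_direction=0)
        with pytest.raises(ValueError):
            synth.SessionConfig(stim_duration=0.0)
        with pytest.raises(ValueError):
            synth.SessionConfig(het_range=45.0)

    def test_category_assignment_follows_horizontal_halves(self):
        cfg = synth.SessionConfig(trials_per_direction=1, seed=0)
        trials = synth.design_session(cfg, np.random.default_rng(0))
        right = set(trials.loc[trials["category"] == "right", "mean_direction"])
        assert right == {22.5, 67.5, 292.5, 337.5}


class TestDotSampling:
    def test_zero_range_returns_copies_of_mean(self):
        dots = synth.sample_dot_directions(67.5, 0.0, 500, np.random.default_rng(0))
        assert dots.shape == (500,)
        assert np.all(dots == 67.5)

    def test_circular_mean_converges_to_nominal_mean(self):
        rng = np.random.default_rng(42)
        dots = synth.sample_dot_directions(90.0, 180.0, 100_000, rng)
        assert abs(wrap180(circmean_deg(dots) - 90.0)) < 0.5

    def test_empirical_range_matches_nominal(self):
        rng = np.random.default_rng(3)
        dots = synth.sample_dot_directions(180.0, 90.0, 100_000, rng)
        spread = dots.max() - dots.min()
        assert abs(spread - 90.0) < 2.0

    def test_no_dot_carries_the_global_mean_itself(self):
        rng = np.random.default_rng(1)
        dots = synth.sample_dot_directions(22.5, 270.0, 50_000, rng)
        assert not np.any(dots == 22.5)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            synth.sample_dot_directions(0.0, 360.0, 10, np.random.default_rng(0))


def _one_trial(direction=22.5, het_range=0.0):
    return pd.Series(
        {
            "mean_direction": direction,
            "het_range": het_range,
            "category": "right" if direction in (22.5, 67.5, 292.5, 337.5) else "left",
        }
    )


class TestTrialRates:
    def setup_method(self):
        self.cfg = synth.SessionConfig(trials_per_direction=1, seed=0)

    def _pop(self, mode, **kw):
        return synth.make_population(8, np.random.default_rng(0), coding_mode=mode, **kw)

    def test_linear_sum_peak_equals_baseline_plus_amplitude(self):
        pop = self._pop("linear_sum", amplitude=2.0, baseline=0.5)
        dots = np.full(100, 22.5)
        rates = synth.simulate_trial_rates(_one_trial(), dots, pop, self.cfg)
        stim = rates[:, self.cfg.pre_frames]
        assert stim[0] == pytest.approx(2.5)  # neuron 0 prefers 22.5
        assert np.all(rates[:, : self.cfg.pre_frames] == 0.5)

    def test_linear_sum_full_circle_approaches_circular_average(self):
        # dots spanning (almost) the full circle: rate -> circular mean of the
        # tuning curve, identical for every neuron up to quadrature error
        pop = self._pop("linear_sum", amplitude=1.0, baseline=0.0)
        kappa = pop.width[0]
        grid = np.arange(0.0, 360.0, 0.25) + 0.125
        rates = [
            synth.simulate_trial_rates(
                _one_trial(d), grid, pop, self.cfg
            )[:, self.cfg.pre_frames]
            for d in (22.5, 112.5)
        ]
        from scipy.special import i0

        expected = np.exp(-kappa) * i0(kappa)  # circular average of the bump
        for r in rates:
            assert np.allclose(r, expected, rtol=1e-3)

    def test_linear_sum_cosine_attenuation_matches_integral(self):
        # uniform dot window of width r attenuates a cosine component by
        # sin(r/2) / (r/2); verified against dense numeric integration
        pop = synth.PopulationModel(
            preferred_direction=np.array([22.5]),
            amplitude=np.array([1.0]),
            width=np.array([2.0]),
            baseline=np.array([0.0]),
            coding_mode="linear_sum",
        )
        r_deg = 180.0
        dots = 22.5 + (np.arange(100_000) + 0.5) / 100_000 * r_deg - r_deg / 2
        rate = synth.simulate_trial_rates(
            _one_trial(22.5, r_deg), dots, pop, self.cfg
        )[0, self.cfg.pre_frames]
        theta = np.linspace(22.5 - r_deg / 2, 22.5 + r_deg / 2, 200_001)
        numeric = np.trapezoid(pop.tuning(theta)[:, 0], theta) / r_deg
        assert rate == pytest.approx(numeric, rel=1e-6)

    def test_sharpened_mean_equals_linear_sum_on_homogeneous_dots(self):
        gains = {0.0: 1.0, 90.0: 1.0, 180.0: 1.0, 270.0: 1.0}
        dots = np.full(50, 157.5)
        a = self._pop("linear_sum", gain_by_range=gains)
        b = self._pop("sharpened_mean", gain_by_range=gains)
        ra = synth.simulate_trial_rates(_one_trial(157.5), dots, a, self.cfg)
        rb = synth.simulate_trial_rates(_one_trial(157.5), dots, b, self.cfg)
        assert np.allclose(ra, rb)

    def test_untuned_population_sits_at_baseline(self):
        pop = self._pop("untuned", baseline=0.2)
        rates = synth.simulate_trial_rates(
            _one_trial(), np.full(10, 22.5), pop, self.cfg
        )
        assert np.all(rates == 0.2)

    def test_category_mode_uses_two_levels(self):
        pop = self._pop("category", amplitude=1.0, baseline=0.0)
        rates = synth.simulate_trial_rates(
            _one_trial(22.5), np.full(10, 22.5), pop, self.cfg
        )
        stim = rates[:, self.cfg.pre_frames]
        assert set(np.round(stim, 12)) == {0.0, 1.0}

    def test_unknown_coding_mode_rejected(self):
        with pytest.raises(ValueError):
            synth.PopulationModel(
                preferred_direction=np.array([0.0]),
                amplitude=np.array([1.0]),
                width=np.array([1.0]),
                baseline=np.array([0.0]),
                coding_mode="mystery",
            )


class TestCalcium:
    def test_zero_rates_zero_noise_gives_zero_traces(self):
        params = synth.CalciumParams(noise_sd=0.0, drift_amplitude=0.0)
        out = synth.simulate_calcium(np.zeros((3, 100)), params, np.random.default_rng(0))
        assert np.all(out == 0)

    def test_unit_impulse_follows_exponential_kernel(self):
        params = synth.CalciumParams(decay_tau=0.5, noise_sd=0.0, drift_amplitude=0.0)
        fr = 20.0
        rates = np.zeros((1, 50))
        rates[0, 10] = 1.0
        out = synth.simulate_calcium(rates, params, np.random.default_rng(0), frame_rate=fr)
        k = np.arange(40)
        assert out[0, :10] == pytest.approx(0.0)
        assert np.allclose(out[0, 10:], np.exp(-k / (params.decay_tau * fr)))
        assert out[0].argmax() == 10

    def test_seeded_reproducibility(self):
        params = synth.CalciumParams()
        rates = np.ones((2, 200))
        a = synth.simulate_calcium(rates, params, np.random.default_rng(5))
        b = synth.simulate_calcium(rates, params, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_calcium(
                -np.ones((1, 10)), synth.CalciumParams(), np.random.default_rng(0)
            )


class TestChoices:
    def _trials(self, n=2000, direction=67.5):
        return pd.DataFrame(
            {
                "mean_direction": np.full(n, direction),
                "category": ["right" if direction in (22.5, 67.5, 292.5, 337.5) else "left"] * n,
            }
        )

    def test_probability_right_matches_cumulative_normal(self):
        psych = synth.PsychParams(sigma=22.5, lapse=0.0)
        trials = synth.simulate_choices(
            self._trials(20_000, 67.5), psych, np.random.default_rng(0)
        )
        p = (trials["choice"] == "right").mean()
        assert p == pytest.approx(norm.cdf(1.0), abs=0.01)  # Phi(22.5/22.5)

    def test_vanishing_sigma_gives_perfect_accuracy(self):
        psych = synth.PsychParams(sigma=1e-6, lapse=0.0)
        trials = synth.simulate_choices(self._trials(500), psych, np.random.default_rng(0))
        assert trials["correct"].all()

    def test_full_lapse_gives_chance_accuracy(self):
        psych = synth.PsychParams(sigma=22.5, lapse=1.0)
        trials = synth.simulate_choices(
            self._trials(20_000), psych, np.random.default_rng(1)
        )
        assert trials["correct"].mean() == pytest.approx(0.5, abs=0.02)


class TestEndToEnd:
    def test_session_is_deterministic_under_fixed_seed(self, small_config):
        rng = np.random.default_rng(0)
        pop = synth.make_population(6, rng)
        a = synth.generate_session(small_config, pop, seed=11)
        b = synth.generate_session(small_config, pop, seed=11)
        assert np.array_equal(a.traces, b.traces)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_trace_layout_matches_trial_count(self, quiet_session, small_config):
        n_trials = len(quiet_session.trials)
        assert quiet_session.traces.shape[1] == (
            n_trials * small_config.frames_per_trial + small_config.pre_frames
        )
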