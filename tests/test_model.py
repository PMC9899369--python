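"""Unit and property tests for the DMC generative model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dmckit.model import (
    DMCParameters,
    automatic_activation,
    automatic_drift,
    compute_caf,
    compute_delta,
    sample_start_point,
    simulate_condition,
    simulate_trial,
    superimposed_drift,
    TrialOutcome,
)


class TestActivation:
    def test_peak_equals_amplitude_at_tau(self):
        p = DMCParameters(amplitude=20, time_to_peak=100)
        assert automatic_activation(100.0, p) == pytest.approx(20.0)

    def test_zero_at_origin(self):
        assert automatic_activation(0.0, DMCParameters()) == 0.0

    def test_closed_form_value(self):
        # A*exp(-36/72)*(36e/72)^1 = 27.5*e^(-1/2)*(e/2)
        p = DMCParameters(amplitude=27.5, time_to_peak=72)
        expected = 27.5 * math.exp(-0.5) * 0.5 * math.e
        assert automatic_activation(36.0, p) == pytest.approx(expected)
        assert automatic_activation(36.0, p) == pytest.approx(22.67, abs=5e-3)

    @pytest.mark.parametrize("shape", [1.5, 2.0, 3.0])
    def test_maximum_at_tau_times_shape_minus_one(self, shape):
        p = DMCParameters(amplitude=30, time_to_peak=80, gamma_shape=shape)
        grid = np.linspace(1e-6, 2000, 200_001)
        vals = automatic_activation(grid, p)
        assert grid[np.argmax(vals)] == pytest.approx(80 * (shape - 1), rel=1e-3)
        assert vals.max() == pytest.approx(30.0, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            automatic_activation(-1.0, DMCParameters())
        with pytest.raises(ValueError):
            automatic_drift(-1.0, DMCParameters())


class TestAutomaticDrift:
    def test_zero_at_peak_and_negative_after(self):
        p = DMCParameters(amplitude=27.5, time_to_peak=72)
        assert automatic_drift(72.0, p) == pytest.approx(0.0, abs=1e-12)
        assert automatic_drift(144.0, p) < 0

    def test_origin_limit_shape_two(self):
        p = DMCParameters(amplitude=27.5, time_to_peak=72)
        assert automatic_drift(0.0, p) == pytest.approx(27.5 * math.e / 72)
        assert automatic_drift(0.0, p) == pytest.approx(1.0383, abs=1e-4)

    @pytest.mark.parametrize("shape", [1.5, 2.0, 3.0])
    def test_matches_numerical_derivative(self, shape):
        p = DMCParameters(amplitude=27.5, time_to_peak=72, gamma_shape=shape)
        t = np.linspace(1.0, 600.0, 5000)
        h = 1e-4
        numeric = (automatic_activation(t + h, p) - automatic_activation(t - h, p)) / (2 * h)
        analytic = automatic_drift(t, p)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-9)


class TestSuperimposedDrift:
    def test_condition_signs(self):
        p = DMCParameters(amplitude=27.5, time_to_peak=72, drift=0.5)
        peak = 72.0
        assert superimposed_drift(peak, "congruent", p) == pytest.approx(0.5)
        assert superimposed_drift(123.0, "neutral", p) == 0.5
        # early incongruent drift points toward the error boundary
        early = superimposed_drift(1.0, "incongruent", p)
        assert early == pytest.approx(0.5 - automatic_drift(1.0, p))
        assert early < 0

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            superimposed_drift(1.0, "kongruent", DMCParameters())


class TestStartPoint:
    def test_uniform_when_shape_one(self, rng):
        p = DMCParameters(start_shape=1.0, boundary=62.5)
        draws = sample_start_point(p, rng, size=20_000)
        assert np.all(np.abs(draws) < 62.5)
        # beta(1,1) is uniform: compare against the uniform CDF
        u = (draws / 62.5 + 1) / 2
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_symmetry_and_sd(self, rng):
        p = DMCParameters(start_shape=2.5, boundary=62.5)
        draws = sample_start_point(p, rng, size=100_000)
        assert abs(draws.mean()) < 0.5
        a = 2.5
        beta_sd = math.sqrt(a * a / ((2 * a) ** 2 * (2 * a + 1)))
        assert draws.std() == pytest.approx(2 * 62.5 * beta_sd, rel=0.02)


class TestSimulation:
    def test_noise_free_limit(self, rng):
        p = DMCParameters(
            amplitude=0.0, drift=0.5, boundary=62.5, nondecision_mean=335,
            nondecision_sd=0.0, diffusion_constant=0.0, start_shape=math.inf,
        )
        t = simulate_trial("congruent", p, rng)
        assert t.rt == pytest.approx(335 + 62.5 / 0.5)
        assert t.correct and not t.censored

    def test_zero_amplitude_conditions_equivalent(self, rng):
        p = DMCParameters(amplitude=0.0)
        con = simulate_condition("congruent", 5000, p, rng)
        inc = simulate_condition("incongruent", 5000, p, rng)
        assert stats.ks_2samp(con.rt, inc.rt).pvalue > 0.01
        # accuracy also indistinguishable
        table = [
            [con.correct.sum(), (~con.correct).sum()],
            [inc.correct.sum(), (~inc.correct).sum()],
        ]
        assert stats.chi2_contingency(table).pvalue > 0.01

    def test_congruency_cost_emerges(self, rng):
        p = DMCParameters(time_to_peak=135)  # flanker-like dynamics
        con = simulate_condition("congruent", 10_000, p, rng)
        inc = simulate_condition("incongruent", 10_000, p, rng)
        assert inc.correct_rts().mean() > con.correct_rts().mean()
        assert inc.accuracy() < con.accuracy()

    def test_determinism_and_preconditions(self, simon_params):
        a = simulate_condition("congruent", 500, simon_params, np.random.default_rng(5))
        b = simulate_condition("congruent", 500, simon_params, np.random.default_rng(5))
        np.testing.assert_array_equal(a.rt, b.rt)
        np.testing.assert_array_equal(a.correct, b.correct)
        with pytest.raises(ValueError):
            simulate_condition("congruent", 0, simon_params, np.random.default_rng(0))

    def test_rt_bounded_by_horizon(self, simon_params, rng):
        p = simon_params.with_(nondecision_sd=30.0)
        batch = simulate_condition("incongruent", 5000, p, rng)
        max_ter = p.nondecision_mean + math.sqrt(3) * p.nondecision_sd
        assert np.all(batch.rt <= p.max_time + max_ter)
        assert np.all(batch.rt >= 0)

    def test_accuracy_monotone_in_boundary(self, rng):
        accs = [
            simulate_condition(
                "incongruent", 10_000, DMCParameters(boundary=b), rng
            ).accuracy()
            for b in (45.0, 62.5, 80.0)
        ]
        assert accs[0] < accs[1] < accs[2]

    def test_dt_halving_stability(self):
        p = DMCParameters()
        rng = np.random.default_rng(11)
        coarse = simulate_condition("incongruent", 10_000, p, rng)
        fine = simulate_condition("incongruent", 10_000, p.with_(dt=0.5), rng)
        # differences stay within joint sampling error of the two runs
        se_rt = math.sqrt(coarse.rt.var() / len(coarse) + fine.rt.var() / len(fine))
        assert abs(coarse.rt.mean() - fine.rt.mean()) < 4 * se_rt
        se_acc = math.sqrt(2 * 0.25 / 10_000)
        assert abs(coarse.accuracy() - fine.accuracy()) < 4 * se_acc


class TestParameterValidation:
    @given(
        st.sampled_from(
            ["amplitude", "time_to_peak", "boundary", "nondecision_mean",
             "diffusion_constant", "dt"]
        ),
        st.floats(max_value=-1e-6, min_value=-1e6),
    )
    @settings(max_examples=30, deadline=None)
    def test_negative_values_rejected(self, name, value):
        with pytest.raises(ValueError):
            DMCParameters(**{name: value})

    def test_dict_round_trip(self):
        p = DMCParameters(amplitude=20.0, time_to_peak=100.0)
        assert DMCParameters.from_dict(p.to_dict()) == p
        with pytest.raises(TypeError):
            DMCParameters.from_dict({"amplitude": 20.0, "bogus": 1.0})

    def test_shape_and_horizon_invariants(self):
        with pytest.raises(ValueError):
            DMCParameters(gamma_shape=1.0)
        with pytest.raises(ValueError):
            DMCParameters(start_shape=0.5)
        with pytest.raises(ValueError):
            DMCParameters(max_time=0.5, dt=1.0)


class TestCAF:
    def _outcomes(self, rts, correct):
        return [
            TrialOutcome(rt=r, correct=c, condition="incongruent",
                         decision_time=r, censored=False)
            for r, c in zip(rts, correct)
        ]

    def test_all_correct(self):
        caf = compute_caf(self._outcomes(range(100, 1100, 100), [True] * 10), n_bins=5)
        np.testing.assert_array_equal(caf.accuracy_per_bin, np.ones(5))

    def test_hand_fixture_two_bins(self):
        # errors at the two fastest of ten trials -> (3/5, 1.0)
        correct = [False, False] + [True] * 8
        caf = compute_caf(self._outcomes(range(100, 1100, 100), correct), n_bins=2)
        np.testing.assert_allclose(caf.accuracy_per_bin, [0.6, 1.0])

    def test_fast_errors_in_incongruent_simulation(self, simon_batches):
        caf = compute_caf(simon_batches["incongruent"], n_bins=5)
        assert caf.accuracy_per_bin[0] < caf.accuracy_per_bin[-1]
        # response capture: accuracy non-decreasing after the first bin
        # (within sampling error at n = 10^4 -> allow tiny dips)
        diffs = np.diff(caf.accuracy_per_bin[1:])
        assert np.all(diffs > -0.03)

    def test_preconditions(self):
        outs = self._outcomes([100, 200, 300], [True] * 3)
        with pytest.raises(ValueError):
            compute_caf(outs, n_bins=5)
        with pytest.raises(ValueError):
            compute_caf(outs, n_bins=1)


class TestDelta:
    def _outcomes(self, rts):
        return [
            TrialOutcome(rt=r, correct=True, condition="x", decision_time=r,
                         censored=False)
            for r in rts
        ]

    def test_identical_and_shifted(self):
        rts = list(range(300, 800, 25))
        base = self._outcomes(rts)
        shifted = self._outcomes([r + 30 for r in rts])
        np.testing.assert_allclose(compute_delta(base, base).delta_values, 0.0)
        np.testing.assert_allclose(compute_delta(base, shifted).delta_values, 30.0)

    def test_larger_tau_steepens_delta_slope(self):
        rng = np.random.default_rng(21)
        slopes = []
        for tau in (72.0, 505.0):
            p = DMCParameters(time_to_peak=tau)
            con = simulate_condition("congruent", 20_000, p, rng)
            inc = simulate_condition("incongruent", 20_000, p, rng)
            d = compute_delta(con, inc)
            slopes.append(np.polyfit(d.quantile_probs, d.delta_values, 1)[0])
        assert slopes[1] > slopes[0]

    def test_requires_correct_trials(self):
        empty = [
            TrialOutcome(rt=300.0, correct=False, condition="x",
                         decision_time=300.0, censored=False)
        ]
        good = self._outcomes([300, 400, 500])
        with pytest.raises(ValueError):
            compute_delta(good, empty)
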