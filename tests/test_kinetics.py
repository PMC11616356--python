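"""Distribution fits, pause threshold, jump detection."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from beadmotility import (
    Trace,
    TraceError,
    WeightingRule,
    derive_pause_threshold,
    detect_jumps,
    fit_double_exponential_em,
    fit_exponential_weighted,
    fit_truncated_exponential,
    remove_jumps,
)


class TestWeightedExponential:
    def test_unit_weights_give_sample_mean(self):
        fit = fit_exponential_weighted([1.0, 2.0, 3.0], weights=[1, 1, 1])
        assert fit.params["mean"] == pytest.approx(2.0, abs=1e-12)
        assert fit.n == 3

    def test_duration_weighting_closed_form(self):
        # durations 30 s and 10 s -> N_R = 3, 1 -> mu = (3*1 + 1*4)/4
        fit = fit_exponential_weighted([1.0, 4.0], durations=[30.0, 10.0])
        assert fit.params["mean"] == pytest.approx(1.75, abs=1e-12)
        assert fit.n_effective == 4

    def test_reported_n_excludes_replication(self):
        fit = fit_exponential_weighted([1.0, 4.0], durations=[30.0, 10.0])
        assert fit.n == 2

    def test_negative_values_rejected(self):
        with pytest.raises(TraceError):
            fit_exponential_weighted([-0.1, 0.5], weights=[1, 1])

    def test_empty_rejected(self):
        with pytest.raises(TraceError):
            fit_exponential_weighted([], weights=[])

    def test_floor_shifts_domain(self):
        fit = fit_exponential_weighted([0.285, 0.485], weights=[1, 1], floor=0.085)
        assert fit.params["mean"] == pytest.approx(0.3, abs=1e-12)

    def test_ci_covers_truth_on_exponential_sample(self):
        rng = np.random.default_rng(0)
        fit = fit_exponential_weighted(rng.exponential(0.17, 200), weights=np.ones(200))
        lo, hi = fit.ci95["mean"]
        assert lo < 0.17 < hi

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(mu=st.floats(0.01, 10.0), n=st.integers(2, 50))
    def test_weighted_mean_identity(self, mu, n):
        rng = np.random.default_rng(42)
        v = rng.exponential(mu, n)
        w = rng.integers(1, 6, n)
        fit = fit_exponential_weighted(v, weights=w)
        assert fit.params["mean"] == pytest.approx(np.sum(w * v) / np.sum(w), rel=1e-12)


class TestTruncatedExponential:
    def test_closed_form(self):
        fit = fit_truncated_exponential([20.0, 30.0], t0=10.0)
        assert fit.params["tau"] == pytest.approx(15.0, abs=1e-12)
        assert fit.params["mean"] == pytest.approx(25.0, abs=1e-12)

    def test_degenerate_all_at_t0(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_truncated_exponential([10.0, 10.0, 10.0], t0=10.0)
        assert fit.params["tau"] == pytest.approx(0.0)

    def test_below_t0_rejected(self):
        with pytest.raises(TraceError):
            fit_truncated_exponential([9.0, 20.0], t0=10.0)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(7)
        d = 10.0 + rng.exponential(17.0, 200)
        fit = fit_truncated_exponential(d, t0=10.0)
        se = 17.0 / np.sqrt(200)
        assert abs(fit.params["tau"] - 17.0) < 2 * se

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(tau=st.floats(0.5, 100.0), n=st.integers(2, 60))
    def test_mle_equals_mean_minus_t0(self, tau, n):
        rng = np.random.default_rng(3)
        d = 10.0 + rng.exponential(tau, n)
        fit = fit_truncated_exponential(d, t0=10.0)
        assert fit.params["tau"] == pytest.approx(d.mean() - 10.0, rel=1e-12)


class TestDoubleExponentialEM:
    def test_mixture_parameter_recovery(self):
        # aggregate over replicate datasets: a single-draw CI check would
        # fail ~5% of the time by construction
        rng = np.random.default_rng(11)
        n = 500
        t1s, t2s, a1s, covered = [], [], [], 0
        for _ in range(12):
            comp = rng.random(n) < 0.5
            d = 10.0 + np.where(comp, rng.exponential(15.0, n), rng.exponential(120.0, n))
            fit = fit_double_exponential_em(d, t0=10.0)
            assert fit.converged
            assert fit.params["A1"] + fit.params["A2"] == pytest.approx(1.0, abs=1e-9)
            assert fit.params["t1"] <= fit.params["t2"]
            t1s.append(fit.params["t1"])
            t2s.append(fit.params["t2"])
            a1s.append(fit.params["A1"])
            covered += (fit.ci95["t1"][0] < 15.0 < fit.ci95["t1"][1]) and (
                fit.ci95["t2"][0] < 120.0 < fit.ci95["t2"][1]
            )
        assert np.mean(t1s) == pytest.approx(15.0, abs=1.5)
        assert np.mean(t2s) == pytest.approx(120.0, abs=9.0)
        assert np.mean(a1s) == pytest.approx(0.5, abs=0.06)
        assert covered >= 8

    def test_em_matches_direct_likelihood_maximization(self):
        # independent oracle: generic optimizer on the same truncated-mixture
        # likelihood reaches the same maximum
        from scipy.optimize import minimize

        rng = np.random.default_rng(11)
        n = 500
        comp = rng.random(n) < 0.5
        d = 10.0 + np.where(comp, rng.exponential(15.0, n), rng.exponential(120.0, n))
        s = d - 10.0

        def nll(th):
            a = 1 / (1 + np.exp(-th[0]))
            t1, t2 = np.exp(th[1]), np.exp(th[2])
            dens = a / t1 * np.exp(-s / t1) + (1 - a) / t2 * np.exp(-s / t2)
            return -np.sum(np.log(np.maximum(dens, 1e-300)))

        opt = minimize(nll, [0.0, np.log(10.0), np.log(100.0)], method="Nelder-Mead",
                       options=dict(maxiter=5000, xatol=1e-8, fatol=1e-10))
        fit = fit_double_exponential_em(d, t0=10.0)
        assert -fit.loglik == pytest.approx(opt.fun, abs=1e-3)
        assert fit.params["t1"] == pytest.approx(np.exp(opt.x[1]), rel=1e-3)
        assert fit.params["t2"] == pytest.approx(np.exp(opt.x[2]), rel=1e-3)

    def test_mixture_loglik_beats_single(self):
        rng = np.random.default_rng(13)
        n = 400
        comp = rng.random(n) < 0.4
        d = 10.0 + np.where(comp, rng.exponential(12.0, n), rng.exponential(90.0, n))
        single = fit_truncated_exponential(d, t0=10.0)
        double = fit_double_exponential_em(d, t0=10.0)
        assert double.loglik >= single.loglik - 1e-6

    def test_null_data_yields_degenerate_improvement(self):
        # data from one shifted exponential: mixture gains < chi2 noise floor
        rng = np.random.default_rng(17)
        d = 10.0 + rng.exponential(20.0, 400)
        single = fit_truncated_exponential(d, t0=10.0)
        double = fit_double_exponential_em(d, t0=10.0)
        assert 0 <= double.loglik - single.loglik < 5.0

    def test_single_component_matches_truncated_mle(self):
        rng = np.random.default_rng(19)
        d = 10.0 + rng.exponential(25.0, 100)
        em = fit_double_exponential_em(d, t0=10.0, n_components=1)
        mle = fit_truncated_exponential(d, t0=10.0)
        assert em.params["tau"] == pytest.approx(mle.params["tau"], abs=1e-5)

    def test_below_t0_rejected(self):
        with pytest.raises(TraceError):
            fit_double_exponential_em([5.0, 20.0, 30.0, 40.0], t0=10.0)


class TestPauseThreshold:
    def test_control_value(self):
        assert derive_pause_threshold(0.037, 0.90) == pytest.approx(0.0852, abs=5e-4)

    def test_unit_quantile(self):
        assert derive_pause_threshold(1.0, 1 - 1 / np.e) == pytest.approx(1.0, abs=1e-12)

    def test_median(self):
        assert derive_pause_threshold(0.1, 0.5) == pytest.approx(0.0693, abs=1e-4)

    def test_invalid_quantile(self):
        with pytest.raises(TraceError):
            derive_pause_threshold(0.037, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(mu=st.floats(1e-3, 10.0), q=st.floats(0.05, 0.99))
    def test_linear_in_mu_and_monotone_in_quantile(self, mu, q):
        assert derive_pause_threshold(mu, q) == pytest.approx(
            mu * derive_pause_threshold(1.0, q), rel=1e-9
        )
        assert derive_pause_threshold(mu, min(q + 0.005, 0.995)) >= derive_pause_threshold(mu, q)


def sigmoid_step_trace(amp=12.0, rise=0.001, at=15.0, duration=30.0, rate=3000.0,
                       noise=0.0, seed=0, extra=()):
    t = np.arange(0, duration, 1 / rate)
    scale = rise / (2 * np.log(99.0))
    x = amp * expit((t - at) / scale)
    for a2, t2 in extra:
        x = x + a2 * expit((t - t2) / scale)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, len(t))
    return Trace(t=t, x=x, sample_rate=rate)


class TestJumpDetection:
    def test_noiseless_step_detected(self):
        tr = sigmoid_step_trace(amp=12.0, rise=0.001)
        events = detect_jumps(tr)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(12.0, abs=0.5)
        assert events[0].transition_time <= 0.0015
        assert abs(events[0].t - 15.0) < 0.1

    def test_noisy_step_detected(self):
        tr = sigmoid_step_trace(amp=8.0, rise=0.005, noise=2.0, seed=1)
        events = detect_jumps(tr)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(8.0, abs=1.0)

    def test_control_noise_yields_no_events(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 200.0, 1 / 3000.0)
        tr = Trace(t=t, x=rng.normal(0, 2.0, len(t)), sample_rate=3000.0)
        assert detect_jumps(tr) == []

    def test_toggle_pair_partnered(self):
        tr = sigmoid_step_trace(amp=10.0, rise=0.001, at=10.0, extra=[(-10.0, 12.0)],
                                noise=2.0, seed=3)
        events = detect_jumps(tr)
        assert len(events) == 2
        assert events[0].reversible_partner == events[1].index
        assert events[1].reversible_partner == events[0].index

    def test_sub_threshold_step_ignored(self):
        tr = sigmoid_step_trace(amp=3.0, rise=0.001, noise=2.0, seed=4)
        assert detect_jumps(tr, min_amplitude=5.0) == []

    def test_remove_jumps_restores_baseline(self):
        tr = sigmoid_step_trace(amp=12.0, rise=0.001)
        events = detect_jumps(tr)
        out = remove_jumps(tr, events)
        # away from the edge, the step is gone
        late = out.x[out.t > 16.0]
        assert np.allclose(late, 0.0, atol=0.6)
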