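"""Accumulator dynamics: stepping primitives, trial simulation, termination."""

import numpy as np
import pytest

from confcontrol import accumulators as acc
from confcontrol import evidence as ev


def make_trace(nu_left, nu_right=None, circ_var=0.25, n=240):
    """Constant-evidence trace from raw per-frame log probabilities."""
    nl = np.full(n, nu_left)
    nr = (np.full(n, nu_right) if nu_right is not None
          else np.log1p(-np.exp(nl)))
    return ev.EvidenceTrace(nu_left=nl, nu_right=nr,
                            circ_var=np.full(n, circ_var), side="left")


class TestPrimitives:
    def test_momentary_noise_degenerate(self):
        rng = np.random.default_rng(0)
        assert acc.momentary_noise(0.0, 0.5, rng) == 0.0
        assert acc.momentary_noise(1.0, 0.0, rng) == 0.0

    def test_momentary_noise_variance(self):
        rng = np.random.default_rng(1)
        x = acc.momentary_noise(1.0, 0.25, rng, size=100_000)
        assert np.var(x) == pytest.approx(0.25, abs=0.005)

    def test_step_primary_additivity(self):
        assert acc.step_primary(0.0, 0.1, 0.0) == pytest.approx(0.1)
        x = acc.step_primary(acc.step_primary(0.0, 0.1, 0.02), 0.3, -0.01)
        assert x == pytest.approx(0.41)

    def test_step_motor_limits(self):
        assert acc.step_motor(0.4, 1.0, 1.0) == pytest.approx(1.0)
        assert acc.step_motor(0.4, 1.0, 0.0) == pytest.approx(0.4)
        with pytest.raises(ev.InvalidParameterError):
            acc.step_motor(0.0, 1.0, 1.5)

    def test_ema_matches_unrolled_closed_form(self):
        # y_T = sum_k a*(1-a)^(T-k) x_k for y_0 = 0, constant a
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        a = 0.23
        y = x[0] * a
        ys = [y]
        for v in x[1:]:
            y = y + a * (v - y)
            ys.append(y)
        T = len(x)
        closed = sum(a * (1 - a) ** (T - 1 - k) * x[k] for k in range(T))
        assert ys[-1] == pytest.approx(closed, abs=1e-10)
        from confcontrol import _kernels
        ypath = _kernels.ema_path(np.full((1, T), a), x[None, :])
        assert ypath[0, -1] == pytest.approx(closed, abs=1e-10)

    def test_online_confidence_cases(self):
        assert acc.online_confidence(1.0, 1.0, 5.0, 2.0) == pytest.approx(0.5)
        # delta x = 1 with zero accumulated variance: logistic(1)
        assert acc.online_confidence(1.0, 0.0, 0.0, 3.0) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12)
        # beta = sigma2_cum halves the weight: logistic(1) again for dx=2
        assert acc.online_confidence(2.0, 0.0, 4.0, 4.0) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12)

    def test_ideal_observer_limit(self):
        # as beta -> inf the read-out is the exact Bayesian posterior
        dx = 1.7
        want = 1 / (1 + np.exp(-dx))
        got = acc.online_confidence(2.0, 2.0 - dx, 37.0, 1e12)
        assert got == pytest.approx(want, abs=1e-9)

    def test_leakage_from_confidence(self):
        assert acc.leakage_from_confidence(0.5, 0.5) == 0.0
        assert acc.leakage_from_confidence(0.8, 0.5) == pytest.approx(0.3)
        assert acc.leakage_from_confidence(0.4, 0.5) == 0.0

    def test_urgency_pc(self):
        assert acc.urgency_pc(0.2, 0.5) == pytest.approx(0.5)
        assert acc.urgency_pc(2.0, 0.3) == 0.0
        assert acc.urgency_pc(1.5, 1.0) == pytest.approx(0.25)
        with pytest.raises(ev.InvalidParameterError):
            acc.urgency_pc(0.5, 2.5)

    def test_sample_ndt(self):
        rng = np.random.default_rng(3)
        assert acc.sample_ndt(0.4, 0.0, rng) == pytest.approx(0.4)
        x = acc.sample_ndt(0.1, 0.2, rng, size=1_000_000)
        assert np.all(x >= 0)
        # folded-normal mean oracle
        from scipy.stats import norm
        mu, s = 0.1, 0.2
        want = s * np.sqrt(2 / np.pi) * np.exp(-mu**2 / (2 * s**2)) \
            + mu * (1 - 2 * norm.cdf(-mu / s))
        assert np.mean(x) == pytest.approx(want, abs=0.002)

    def test_bound_at(self):
        p = acc.ClassicParams(sigma=1.0, b=2.0)
        assert acc.bound_at(1.3, p) == 2.0
        w = acc.ClassicParams(sigma=1.0, b=2.0,
                              weibull=acc.WeibullBound(0.8, 2.0, 0.25))
        assert acc.bound_at(0.0, w) == pytest.approx(2.0)
        t = np.linspace(0, 10, 200)
        bt = acc.bound_at(t, w)
        assert np.all(np.diff(bt) <= 1e-12)
        assert bt[-1] == pytest.approx(0.25 * 2.0, abs=1e-3)
        with pytest.raises(ev.InvalidParameterError):
            acc.WeibullBound(-1.0, 2.0, 0.2)


class TestSimulateTrial:
    def test_deterministic_crossing(self):
        # noise-free: increments of 0.1 per frame reach b=1 at frame 10
        # (the 1e-12 nudge keeps ten rounded float increments at or above 1)
        trace = make_trace(np.log(0.5) + 0.1 + 1e-12)
        p = acc.ClassicParams(sigma=0.0, b=1.0, mu_U=0.0, sigma_U=0.0)
        out = acc.simulate_trial("classic", p, trace, np.random.default_rng(0))
        assert out.choice == "left"
        assert out.decision_time == pytest.approx(10 / 120)
        assert not out.timed_out

    def test_motor_frozen_while_confidence_at_chance(self, moderate_trace):
        p = acc.ConfControlParams(sigma=1.0, beta=2.0, t_d=2.0, b=6.0)
        paths = acc.simulate_paths("conf_control", p, moderate_trace, 50,
                                   np.random.default_rng(4))
        at_chance = paths["c_left"] <= 0.5
        assert np.all(paths["alpha_left"][at_chance] == 0.0)
        # y stays put wherever alpha is 0
        y = paths["y_left"]
        frozen = paths["alpha_left"][:, 1:] == 0.0
        assert np.allclose(y[:, 1:][frozen],
                           np.broadcast_to(y[:, :-1], y[:, 1:].shape)[frozen])

    def test_symmetric_stimulus_gives_even_odds(self):
        trace = make_trace(np.log(0.5))
        p = acc.ClassicParams(sigma=1.0, b=4.0, mu_U=0.0, sigma_U=0.0)
        batch = acc.simulate_batch("classic", p, trace, 10_000,
                                   np.random.default_rng(5))
        assert np.mean(batch.choice == acc.LEFT) == pytest.approx(0.5, abs=0.015)

    def test_bound_monotonicity(self, moderate_trace):
        accs, dts = [], []
        for b in (2.0, 4.0, 8.0):
            p = acc.ClassicParams(sigma=1.0, b=b, mu_U=0.0, sigma_U=0.0)
            batch = acc.simulate_batch("classic", p, moderate_trace, 5000,
                                       np.random.default_rng(6))
            accs.append(np.mean(batch.choice == acc.LEFT))
            dts.append(np.mean(batch.decision_time))
        assert accs[0] < accs[1] < accs[2]
        assert dts[0] < dts[1] < dts[2]

    def test_sigma2_cum_is_running_sum(self, moderate_trace, default_params):
        paths = acc.simulate_paths("conf_control", default_params,
                                   moderate_trace, 3, np.random.default_rng(7))
        assert np.allclose(np.cumsum(paths["sigma2_momentary"]),
                           paths["sigma2_cum"], atol=1e-12)
        assert np.all(np.diff(paths["sigma2_cum"]) >= 0)

    def test_determinism_bitwise(self, moderate_trace, default_params):
        a = acc.simulate_trial("conf_control", default_params, moderate_trace,
                               None, seed=42)
        b = acc.simulate_trial("conf_control", default_params, moderate_trace,
                               None, seed=42)
        assert a == b

    def test_kernel_matches_reference_paths(self, moderate_trace, default_params):
        n = 200
        z = np.random.default_rng(8).standard_normal((2, n, 480))
        tie = np.random.default_rng(9).random(n)
        batch = acc.simulate_batch("conf_control", default_params,
                                   moderate_trace, n, np.random.default_rng(0),
                                   noise=(z[0], z[1]), ndt_z=np.zeros(n), tie=tie)
        paths = acc.simulate_paths("conf_control", default_params,
                                   moderate_trace, n, np.random.default_rng(0),
                                   noise=(z[0], z[1]))
        ch, fr, to = acc.outcomes_from_paths("conf_control", default_params,
                                             paths, tie=tie)
        assert np.array_equal(ch, batch.choice)
        assert np.array_equal(fr, batch.decision_frame)
        assert np.array_equal(to, batch.timed_out)

    def test_static_lit_is_constant_ema_race(self, moderate_trace):
        p = acc.StaticLITParams(sigma=0.8, b=4.0, alpha_static=0.5,
                                mu_U=0.0, sigma_U=0.0)
        n = 20
        z = np.random.default_rng(10).standard_normal((2, n, 480))
        paths = acc.simulate_paths("static_lit", p, moderate_trace, n,
                                   np.random.default_rng(0), noise=(z[0], z[1]))
        # y must equal the constant-alpha EMA of x
        a = 0.5
        y_ref = np.empty_like(paths["x_left"])
        y = np.zeros(n)
        for t in range(paths["x_left"].shape[1]):
            y = y + a * (paths["x_left"][:, t] - y)
            y_ref[:, t] = y
        assert np.allclose(paths["y_left"], y_ref, atol=1e-10)


class TestTerminationRules:
    def test_alpha_one_reduces_to_primary_race(self, moderate_trace):
        # with full leakage the motor accumulator equals the primary one,
        # so both termination rules agree trial by trial at equal bounds
        p = acc.StaticLITParams(sigma=1.0, b=5.0, alpha_static=1.0,
                                mu_U=0.0, sigma_U=0.0)
        pc = acc.ClassicParams(sigma=1.0, b=5.0, mu_U=0.0, sigma_U=0.0)
        n = 500
        z = np.random.default_rng(11).standard_normal((2, n, 480))
        tie = np.random.default_rng(12).random(n)
        kw = dict(noise=(z[0], z[1]), ndt_z=np.zeros(n), tie=tie)
        a = acc.simulate_batch("static_lit", p, moderate_trace, n,
                               np.random.default_rng(0), **kw)
        b = acc.simulate_batch("classic", pc, moderate_trace, n,
                               np.random.default_rng(0), **kw)
        assert np.array_equal(a.choice, b.choice)
        assert np.array_equal(a.decision_frame, b.decision_frame)

    def test_comparison_is_deterministic(self, stimulus_bank, default_params):
        traces = list(stimulus_bank.values())[:6]
        a = acc.compare_termination_rules(default_params, traces, 50, seed=3)
        b = acc.compare_termination_rules(default_params, traces, 50, seed=3)
        assert a == b
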