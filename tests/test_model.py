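"""The correlogram GLM: filter, objective, gradient, LM fitting, tau choice."""

import math

import numpy as np
import pytest

from glmcc import (GLMCC, RelativeSpikeTimes, SynapticFilter,
                   collect_relative_times, filter_value, select_tau)
from glmcc.synthetic import GlmPairConfig, generate_glm_pair


class TestSynapticFilter:
    def test_zero_at_and_before_delay(self):
        f = SynapticFilter(0.004, 0.001)
        assert filter_value(0.001, f) == 0.0
        assert filter_value(-0.005, f) == 0.0

    def test_one_tau_past_delay(self):
        f = SynapticFilter(0.004, 0.001)
        assert filter_value(0.005, f) == pytest.approx(math.exp(-1))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            SynapticFilter(0.0)
        with pytest.raises(ValueError):
            SynapticFilter(0.004, -0.001)


def _rel(lags, W=0.05, **kw):
    return RelativeSpikeTimes(np.asarray(lags, dtype=float), W, **kw)


class TestLogPosterior:
    def test_integral_only_with_flat_baseline(self):
        # no lags, J=0, a = const A, no effective penalty: -2W e^A
        m = GLMCC(_rel([]), tau=0.004)
        A = math.log(100.0)
        theta = np.concatenate((np.full(m.n_bins, A), [0.0, 0.0]))
        assert m.log_posterior(theta) == pytest.approx(-2 * 0.05 * 100.0)

    def test_single_lag_flat_intensity(self):
        # one lag with c = 100 lags/s over a 0.1 s window: log 100 - 10
        m = GLMCC(_rel([0.002]), tau=0.004)
        theta = np.concatenate((np.full(m.n_bins, math.log(100.0)), [0, 0]))
        assert m.log_posterior(theta) == pytest.approx(math.log(100) - 10.0)

    def test_smoothness_penalty_units(self):
        # two bins of 50 ms with a = (0, 1): penalty 1/(gamma * 50 ms) = 40
        m = GLMCC(_rel([]), tau=0.004, gamma=5e-4, n_bins=2)
        flat = np.array([0.0, 0.0, 0.0, 0.0])
        step = np.array([0.0, 1.0, 0.0, 0.0])
        # subtract the (tiny) change in the Poisson integral term
        d_int = (-0.05 * (math.e - 1.0))
        penalty = m.log_posterior(flat) - m.log_posterior(step) + d_int
        assert penalty == pytest.approx(40.0, rel=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        lags = rng.uniform(-0.05, 0.05, 400)
        m = GLMCC(_rel(lags), tau=0.004)
        theta = np.concatenate((rng.normal(8.0, 0.3, m.n_bins), [0.6, -0.4]))
        g = m.score(theta)
        eps = 1e-6
        for i in rng.choice(theta.size, 12, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (m.log_posterior(tp) - m.log_posterior(tm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFit:
    def test_empty_lags_degenerate_contract(self):
        res = GLMCC(_rel([])).fit()
        assert res.j12 == 0.0 and res.j21 == 0.0 and res.converged
        assert np.all(np.isfinite(np.exp(res.a)))

    def test_intensity_flat_when_uncoupled(self):
        res = GLMCC(_rel([])).fit()
        assert res.intensity(0.01) == pytest.approx(res.intensity(-0.02))
        with pytest.raises(ValueError):
            res.intensity(0.2)

    def test_intensity_closed_form_with_unit_coupling(self):
        from glmcc.model import GLMCCResults
        res = GLMCCResults(j12=1.0, j21=0.0, a=np.zeros(100), tau=0.004,
                           gamma=5e-4, delay=0.001, W=0.05, shadow=0.0,
                           log_posterior=0.0, converged=True, n_iter=0,
                           n_lags=0)
        # c(0.005) = exp(1 * e^{-(0.005-0.001)/0.004}) = exp(e^{-1})
        assert res.intensity(0.005) == pytest.approx(math.exp(math.exp(-1)))
        # mirror: with the coupling on the other side the value moves there
        res_m = GLMCCResults(j12=0.0, j21=1.0, a=np.zeros(100), tau=0.004,
                             gamma=5e-4, delay=0.001, W=0.05, shadow=0.0,
                             log_posterior=0.0, converged=True, n_iter=0,
                             n_lags=0)
        assert res_m.intensity(-0.005) == pytest.approx(res.intensity(0.005))

    def test_mirrored_lags_swap_couplings(self, rng):
        lags = rng.uniform(-0.05, 0.05, 2000)
        lags = lags[np.abs(np.abs(lags) - 0.05) > 1e-4]  # keep off edges
        r1 = GLMCC(_rel(lags), tau=0.002).fit()
        r2 = GLMCC(_rel(-lags), tau=0.002).fit()
        assert r1.j12 == pytest.approx(r2.j21, abs=1e-6)
        assert r1.j21 == pytest.approx(r2.j12, abs=1e-6)
        np.testing.assert_allclose(r1.a, r2.a[::-1], atol=1e-5)

    def test_recovers_coupling_from_self_generated_data(self, coupled_pair):
        rel = collect_relative_times(coupled_pair, "1", "2", W=0.05)
        res = GLMCC(rel, tau=0.004).fit()
        se = res.standard_error()
        assert res.converged
        assert res.j12 == pytest.approx(1.0, abs=3 * se)
        assert abs(res.j21) < 3 * se

    def test_flat_baseline_recovered_under_stiff_prior(self, poisson_pair):
        rel = collect_relative_times(poisson_pair, "0", "1", W=0.05)
        res = GLMCC(rel, tau=0.004, gamma=1e-8).fit()
        assert np.ptp(res.a) < 1e-3
        assert res.baseline_c0() == pytest.approx(rel.n / 0.1, rel=0.05)

    def test_loose_prior_tracks_empirical_log_rate(self, rng):
        # strong slow modulation in the lags; a flexible baseline follows it
        lags = np.concatenate([rng.uniform(-0.05, 0.0, 2000),
                               rng.uniform(0.0, 0.05, 6000)])
        res = GLMCC(_rel(lags), tau=0.001, gamma=1.0).fit()
        left = np.exp(res.a[:40]).mean()
        right = np.exp(res.a[60:]).mean()
        assert right / left == pytest.approx(3.0, rel=0.25)

    def test_shadow_excluded_bins_are_interpolated(self, coupled_pair):
        rel = collect_relative_times(coupled_pair, "1", "2", W=0.05,
                                     shadow=0.001)
        res = GLMCC(rel, tau=0.004).fit()
        assert res.converged
        assert np.all(np.isfinite(res.a))
        # shadowing must not create spurious inhibition
        assert res.j12 == pytest.approx(1.0, abs=4 * res.standard_error())

    def test_delay_grid_prefers_true_delay(self):
        cfg = GlmPairConfig(j12=1.5, T=2000.0, seed=3,
                            filter=SynapticFilter(0.002, 0.003))
        tr = generate_glm_pair(cfg)
        rel = collect_relative_times(tr, "1", "2")
        res = GLMCC(rel, tau=0.002,
                    delay_grid=(0.001, 0.002, 0.003, 0.004)).fit()
        assert res.delay == pytest.approx(0.003)

    def test_summary_mentions_couplings(self, coupled_pair):
        rel = collect_relative_times(coupled_pair, "1", "2")
        txt = GLMCC(rel, tau=0.004).fit().summary()
        assert "J12" in txt and "log posterior" in txt

    def test_serialization_round_trip_fields(self, coupled_pair):
        rel = collect_relative_times(coupled_pair, "1", "2")
        d = GLMCC(rel, tau=0.004).fit().to_dict()
        for key in ("J12", "J21", "delay", "tau", "gamma", "a",
                    "log_posterior", "converged"):
            assert key in d


class TestSelectTau:
    def test_single_candidate(self, poisson_pair):
        rel = collect_relative_times(poisson_pair, "0", "1")
        assert select_tau([rel], [0.002]) == 0.002

    def test_recovers_generator_time_scale(self):
        pairs = []
        for seed in (11, 12, 13):
            cfg = GlmPairConfig(j12=1.2, T=3000.0, seed=seed,
                                filter=SynapticFilter(0.004, 0.001))
            tr = generate_glm_pair(cfg)
            pairs.append(collect_relative_times(tr, "1", "2"))
        tau = select_tau(pairs, [0.001, 0.002, 0.004, 0.008])
        assert tau == 0.004

    def test_fast_kinetics_selected_when_true(self):
        pairs = []
        for seed in (21, 22, 23):
            cfg = GlmPairConfig(j12=2.0, T=3000.0, seed=seed,
                                filter=SynapticFilter(0.001, 0.001))
            tr = generate_glm_pair(cfg)
            pairs.append(collect_relative_times(tr, "1", "2"))
        assert select_tau(pairs, [0.001, 0.004]) == 0.001

    def test_empty_grid_rejected(self, poisson_pair):
        rel = collect_relative_times(poisson_pair, "0", "1")
        with pytest.raises(ValueError):
            select_tau([rel], [])
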