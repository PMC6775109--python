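"""Significance test, classification, PSP conversion, network assembly."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from glmcc import (GLMCC, NetworkConfig, classify_pair, collect_relative_times,
                   ei_dominance, estimate_network, generate_independent_poisson,
                   j_to_psp, significance_threshold)
from glmcc.synthetic import GlmPairConfig, generate_glm_pair


class TestSignificanceThreshold:
    def test_critical_values_match_tabulated(self):
        assert norm.isf(0.01 / 2) == pytest.approx(2.58, abs=0.005)
        assert norm.isf(0.001 / 2) == pytest.approx(3.29, abs=0.005)

    def test_hand_evaluated_threshold(self):
        thr = significance_threshold(0.001, 540000.0, 0.001)
        assert thr == pytest.approx(5.1653 / math.sqrt(540), rel=1e-3)

    def test_inverse_sqrt_scaling_in_c0(self):
        t1 = significance_threshold(0.002, 1000.0, 0.01)
        t4 = significance_threshold(0.002, 4000.0, 0.01)
        assert t4 == pytest.approx(t1 / 2, rel=1e-12)

    def test_equals_duration_bound_at_poisson_c0(self):
        # with c0 = T lam_pre lam_post both forms coincide
        from glmcc import confidence_bound_J
        T, l1, l2, tau, alpha = 5400.0, 10.0, 10.0, 0.001, 0.001
        assert significance_threshold(tau, T * l1 * l2, alpha) == pytest.approx(
            confidence_bound_J(T, l1, l2, tau, alpha), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            significance_threshold(0.0, 100.0, 0.01)
        with pytest.raises(ValueError):
            significance_threshold(0.001, 100.0, 1.5)


class TestJToPsp:
    def test_unit_coupling_coefficients(self):
        assert j_to_psp(0.39, "excitatory") == pytest.approx(1.0)
        assert j_to_psp(-1.57, "inhibitory") == pytest.approx(-1.0)

    def test_undetermined_maps_to_zero(self):
        assert j_to_psp(0.7, "undetermined") == 0.0


class TestClassifyPair:
    def _fit(self, trains, tau=0.004):
        rel = collect_relative_times(trains, "1", "2")
        return GLMCC(rel, tau=tau).fit()

    def test_strong_excitatory_pair(self, coupled_pair):
        fwd, bwd = classify_pair(self._fit(coupled_pair), alpha=0.001,
                                 pair=("1", "2"))
        assert fwd.verdict == "excitatory"
        assert fwd.pre == "1" and fwd.post == "2"
        assert fwd.w_hat == pytest.approx(fwd.j_hat / 0.39)
        assert bwd.verdict == "undetermined" and bwd.w_hat == 0.0

    def test_inhibitory_pair(self):
        tr = generate_glm_pair(GlmPairConfig(j12=-2.0, T=3600.0, seed=9))
        fwd, _ = classify_pair(self._fit(tr), alpha=0.001, pair=("1", "2"))
        assert fwd.verdict == "inhibitory"
        assert fwd.w_hat == pytest.approx(fwd.j_hat / 1.57)
        assert fwd.w_hat < 0

    def test_alpha_monotonicity(self, coupled_pair):
        # more stringent alpha can only shrink the detection set
        fit = self._fit(coupled_pair)
        for weaker, stronger in [(0.01, 0.001), (0.001, 1e-6)]:
            w_f, w_b = classify_pair(fit, alpha=weaker)
            s_f, s_b = classify_pair(fit, alpha=stronger)
            for w, s in [(w_f, s_f), (w_b, s_b)]:
                if s.verdict != "undetermined":
                    assert w.verdict == s.verdict

    def test_verdict_constraints_hold(self, poisson_pair):
        rel = collect_relative_times(poisson_pair, "0", "1")
        fit = GLMCC(rel, tau=0.001).fit()
        for est in classify_pair(fit, alpha=0.001):
            if est.verdict == "excitatory":
                assert est.j_hat > est.j_threshold > 0
            elif est.verdict == "inhibitory":
                assert est.j_hat < -est.j_threshold
            else:
                assert abs(est.j_hat) <= est.j_threshold
                assert est.w_hat == 0.0


class TestEstimateNetwork:
    @pytest.fixture(scope="class")
    def mini_net(self):
        """3 Poisson neurons plus one strongly coupled pair."""
        pair = generate_glm_pair(GlmPairConfig(j12=1.5, T=1800.0, seed=5))
        noise = generate_independent_poisson([8.0], 1800.0, seed=6)
        from glmcc import SpikeTrainSet
        return SpikeTrainSet({"a": pair["1"], "b": pair["2"],
                              "c": noise["0"]}, t_end=1800.0)

    def test_detects_planted_edge(self, mini_net):
        res = estimate_network(mini_net, NetworkConfig(tau=0.004))
        edges = res.significant_edges()
        planted = edges[(edges.pre == "a") & (edges.post == "b")]
        assert len(planted) == 1
        assert planted.iloc[0].verdict == "excitatory"

    def test_matrix_mirrors_estimates(self, mini_net):
        res = estimate_network(mini_net, NetworkConfig(tau=0.004))
        ids = res.matrix.ids
        for est in res.estimates:
            i, j = ids.index(est.post), ids.index(est.pre)
            assert res.matrix.w[i, j] == est.w_hat

    def test_deterministic(self, mini_net):
        r1 = estimate_network(mini_net, NetworkConfig(tau=0.004))
        r2 = estimate_network(mini_net, NetworkConfig(tau=0.004))
        np.testing.assert_array_equal(r1.matrix.w, r2.matrix.w)

    def test_rate_floor_excludes_quiet_neurons(self, mini_net):
        cfg = NetworkConfig(tau=0.004, rate_floor=100.0)
        with pytest.raises(ValueError):
            estimate_network(mini_net, cfg)

    def test_single_neuron_rejected(self):
        tr = generate_independent_poisson([5.0], 100.0, seed=1)
        with pytest.raises(ValueError):
            estimate_network(tr)

    def test_summary_counts_edges(self, mini_net):
        res = estimate_network(mini_net, NetworkConfig(tau=0.004))
        assert "excitatory edges" in res.summary()


class TestEiDominance:
    class _E:
        def __init__(self, pre, verdict):
            self.pre, self.verdict = pre, verdict

    def test_counts_and_index(self):
        ests = ([self._E("n", "excitatory")] * 3
                + [self._E("n", "inhibitory")] * 1
                + [self._E("m", "undetermined")] * 4)
        d = ei_dominance(ests)
        assert d.n_e["n"] == 3 and d.n_i["n"] == 1
        assert d.index("n") == pytest.approx(0.5)

    @pytest.mark.parametrize("ne,ni,expected", [(2, 2, 0.0), (0, 2, -1.0)])
    def test_balanced_and_pure_inhibitory(self, ne, ni, expected):
        ests = ([self._E("x", "excitatory")] * ne
                + [self._E("x", "inhibitory")] * ni)
        assert ei_dominance(ests).index("x") == pytest.approx(expected)

    def test_no_connections_gives_nan(self):
        d = ei_dominance([], neuron_ids=["q"])
        assert math.isnan(d.index("q"))
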