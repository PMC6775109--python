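"""Reconstruction scoring: confusion bookkeeping, MCC, alpha sweep,
PSP-coefficient calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glmcc import (ConfusionCounts, GroundTruthNetwork, calibrate_a,
                   count_confusion, macro_mcc, mcc)
from glmcc.inference import ConnectivityMatrix


def _truth(w, types=None):
    n = len(w)
    ids = [f"n{i}" for i in range(n)]
    if types is None:
        types = {}
        for j, nid in enumerate(ids):
            col = np.delete(np.asarray(w)[:, j], j)
            types[nid] = "inhibitory" if (col < 0).any() else "excitatory"
    else:
        types = dict(zip(ids, types))
    return GroundTruthNetwork(ids, np.asarray(w, dtype=float), types)


def _est(w):
    n = len(w)
    return ConnectivityMatrix([f"n{i}" for i in range(n)],
                              np.asarray(w, dtype=float))


class TestCountConfusion:
    def test_perfect_reconstruction(self):
        w = [[0, 2.0, 0], [0, 0, -1.5], [3.0, 0, 0]]
        counts = count_confusion(_truth(w), _est(w))
        for cat in ("excitatory", "inhibitory"):
            assert counts[cat].fp == 0 and counts[cat].fn == 0

    def test_weak_epsp_excluded_not_counted_as_fn(self):
        w_true = [[0, 0.5], [0, 0]]      # one weak EPSP (<= 1 mV)
        w_est = [[0, 0], [0, 0]]         # missed
        counts = count_confusion(_truth(w_true), _est(w_est))
        assert counts["excitatory"].fn == 0
        assert counts["excitatory"].excluded == 1

    def test_sign_misclassification_double_counts(self):
        # a 2 mV EPSP detected as inhibitory: excitatory FN + inhibitory FP
        w_true = [[0, 2.0, 0], [0, 0, 0], [0, 0, 0]]
        w_est = [[0, -0.8, 0], [0, 0, 0], [0, 0, 0]]
        counts = count_confusion(_truth(w_true), _est(w_est))
        assert counts["excitatory"].fn == 1
        assert counts["inhibitory"].fp == 1

    def test_totals_conserved(self, rng):
        n = 8
        w_true = rng.choice([0, 0, 0.5, 2.0, -1.0], size=(n, n))
        np.fill_diagonal(w_true, 0)
        # make rows sign-consistent per presynaptic column
        for j in range(n):
            col = w_true[:, j]
            if (col < 0).any():
                w_true[:, j] = -np.abs(col)
        w_est = rng.choice([0, 1.5, -1.2], size=(n, n))
        np.fill_diagonal(w_est, 0)
        counts = count_confusion(_truth(w_true), _est(w_est))
        for cat in ("excitatory", "inhibitory"):
            assert counts[cat].total == n * (n - 1)

    def test_neuron_set_mismatch_rejected(self):
        t = _truth([[0, 1.0], [0, 0]])
        e = ConnectivityMatrix(["x", "y"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            count_confusion(t, e)


class TestMcc:
    def test_hand_computed_value(self):
        assert mcc(ConfusionCounts(2, 2, 1, 1)) == pytest.approx(1 / 3)

    def test_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(5, 7, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 7, 5)) == -1.0

    def test_inversion_flips_sign(self):
        c = ConfusionCounts(6, 9, 2, 3)
        ci = ConfusionCounts(3, 2, 9, 6)
        assert mcc(ci) == pytest.approx(-mcc(c))

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 10, 0, 0)) == 0.0

    @given(st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30), st.integers(0, 30))
    def test_matches_label_list_oracle(self, tp, tn, fp, fn):
        # brute force: rebuild label lists and compute the correlation
        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        if len(y_true) == 0:
            return
        yt, yp = np.array(y_true), np.array(y_pred)
        if yt.std() == 0 or yp.std() == 0:
            expected = 0.0
        else:
            expected = np.corrcoef(yt, yp)[0, 1]
        assert mcc(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(
            expected, abs=1e-12)


class TestMacroMcc:
    @pytest.mark.parametrize("a,b,out", [(1, 1, 1), (1, 1 / 3, 2 / 3),
                                         (0.4, 0.4, 0.4)])
    def test_average(self, a, b, out):
        assert macro_mcc(a, b) == pytest.approx(out)

    def test_symmetric(self):
        assert macro_mcc(0.2, 0.9) == macro_mcc(0.9, 0.2)


class TestSelectAlpha:
    @pytest.fixture(scope="class")
    def null_setup(self):
        from glmcc import generate_independent_poisson
        trains = generate_independent_poisson([10.0, 10.0], 300.0, seed=31)
        ids = ["0", "1"]
        truth = GroundTruthNetwork(ids, np.zeros((2, 2)),
                                   {i: "excitatory" for i in ids})
        return truth, trains

    def test_single_candidate_returned(self, null_setup):
        from glmcc import select_alpha
        truth, trains = null_setup
        alpha, sweep = select_alpha(truth, trains, [0.005])
        assert alpha == 0.005 and len(sweep) == 1

    def test_flat_score_falls_back_to_largest_alpha(self, null_setup):
        # a disconnected truth gives MCC 0 everywhere: convention says
        # return the least conservative level
        from glmcc import select_alpha
        truth, trains = null_setup
        alpha, sweep = select_alpha(truth, trains, [1e-6, 1e-4, 1e-2])
        assert alpha == 1e-2

    def test_empty_grid_rejected(self, null_setup):
        from glmcc import select_alpha
        truth, trains = null_setup
        with pytest.raises(ValueError):
            select_alpha(truth, trains, [])


class TestCalibrateA:
    def test_noiseless_slope(self):
        w = np.array([0.5, 1.0, 2.0, 5.0])
        assert calibrate_a(w, 0.39 * w) == pytest.approx(0.39)

    def test_noisy_regression_recovery(self, rng):
        w = rng.uniform(0.2, 3.0, 100)
        j = 1.57 * w + rng.normal(0, 0.1, 100)
        assert calibrate_a(w, j) == pytest.approx(1.57, abs=0.1)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            calibrate_a([1.0], [0.4])
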