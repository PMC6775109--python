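"""Scoring inferred networks against ground truth.

Connections are scored per directed pair in two one-vs-rest categories
(excitatory vs the rest, inhibitory vs the rest) with the Matthews
correlation coefficient; the macro-average of the two MCCs summarizes a
reconstruction in one number.  True excitatory connections at or below
a strength floor (1 mV by default) are excluded from the excitatory
category entirely, because such weak synapses are undetectable within
realistic recording times and would otherwise dominate the
false-negative count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .inference import NetworkConfig, estimate_network

__all__ = [
    "GroundTruthNetwork",
    "ConfusionCounts",
    "count_confusion",
    "mcc",
    "macro_mcc",
    "select_alpha",
    "calibrate_a",
]

logger = logging.getLogger(__name__)


@dataclass
class GroundTruthNetwork:
    """True PSP matrix of a simulated network.

    ``w[i, j]`` is the PSP (mV) of the connection from neuron ``ids[j]``
    onto neuron ``ids[i]``; 0 means unconnected, the sign gives the
    type.  ``cell_types`` maps neuron id to "excitatory"/"inhibitory".
    """

    ids: list
    w: np.ndarray
    cell_types: dict

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        for j, nid in enumerate(self.ids):
            col = np.delete(self.w[:, j], j)
            t = self.cell_types.get(nid)
            if t == "excitatory" and np.any(col < 0):
                raise ValueError(f"excitatory neuron {nid!r} has negative PSPs")
            if t == "inhibitory" and np.any(col > 0):
                raise ValueError(f"inhibitory neuron {nid!r} has positive PSPs")


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for one category (E or I)."""

    tp: int
    tn: int
    fp: int
    fn: int
    excluded: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn + self.excluded


def count_confusion(truth: GroundTruthNetwork, est,
                    epsp_floor: float = 1.0) -> dict:
    """Confusion counts per category over all ordered pairs.

    ``est`` is a :class:`~glmcc.inference.ConnectivityMatrix` (or any
    object with ``ids`` and ``w``).  Pairs whose true EPSP is positive
    but at or below ``epsp_floor`` are excluded from the excitatory
    category (neither positives nor negatives); they still count as
    non-inhibitory in the inhibitory category.  A connection detected
    with the wrong sign is a false negative in its true category and a
    false positive in the predicted one.
    """
    if list(truth.ids) != list(est.ids):
        raise ValueError("truth and estimate cover different neuron sets")
    n = len(truth.ids)
    off = ~np.eye(n, dtype=bool)
    tw = truth.w[off]
    ew = est.w[off]

    weak_e = (tw > 0) & (tw <= epsp_floor)
    # excitatory category: positive = true EPSP above floor
    pos_e = tw > epsp_floor
    pred_e = ew > 0
    scored = ~weak_e
    cc_e = ConfusionCounts(
        tp=int(np.sum(scored & pos_e & pred_e)),
        tn=int(np.sum(scored & ~pos_e & ~pred_e)),
        fp=int(np.sum(scored & ~pos_e & pred_e)),
        fn=int(np.sum(scored & pos_e & ~pred_e)),
        excluded=int(np.sum(weak_e)),
    )
    # inhibitory category: all pairs scored
    pos_i = tw < 0
    pred_i = ew < 0
    cc_i = ConfusionCounts(
        tp=int(np.sum(pos_i & pred_i)),
        tn=int(np.sum(~pos_i & ~pred_i)),
        fp=int(np.sum(~pos_i & pred_i)),
        fn=int(np.sum(pos_i & ~pred_i)),
    )
    return {"excitatory": cc_e, "inhibitory": cc_i}


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def macro_mcc(mcc_e: float, mcc_i: float) -> float:
    """Macro-average of the excitatory and inhibitory coefficients."""
    return 0.5 * (mcc_e + mcc_i)


def score_reconstruction(truth: GroundTruthNetwork, est,
                         epsp_floor: float = 1.0) -> dict:
    """Counts, per-category MCCs and the macro-average, in one report."""
    counts = count_confusion(truth, est, epsp_floor=epsp_floor)
    m_e = mcc(counts["excitatory"])
    m_i = mcc(counts["inhibitory"])
    return {"counts": counts, "mcc_e": m_e, "mcc_i": m_i,
            "macro_mcc": macro_mcc(m_e, m_i)}


def select_alpha(truth: GroundTruthNetwork, trains, alpha_grid,
                 config: NetworkConfig | None = None,
                 epsp_floor: float = 1.0):
    """Sweep the significance level and keep the macro-MCC maximizer.

    Returns ``(alpha_star, sweep)`` where ``sweep`` is a list of
    ``(alpha, macro_mcc)``.  Ties, and the degenerate all-undefined
    case, resolve to the larger (least conservative) alpha.
    """
    alpha_grid = sorted(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha_grid must be non-empty")
    if config is None:
        config = NetworkConfig()
    sweep = []
    for alpha in alpha_grid:
        cfg = NetworkConfig(**{**config.__dict__, "alpha": alpha})
        res = estimate_network(trains, cfg)
        report = score_reconstruction(truth, res.matrix, epsp_floor=epsp_floor)
        sweep.append((alpha, report["macro_mcc"]))
    scores = np.array([s for _, s in sweep])
    if np.allclose(scores, scores[0]):
        logger.warning("macro-MCC flat across the alpha grid; returning the "
                       "largest alpha")
        return alpha_grid[-1], sweep
    # argmax with ties resolved to the larger alpha
    best = len(scores) - 1 - int(np.argmax(scores[::-1]))
    return alpha_grid[best], sweep


def calibrate_a(w_true, j_fitted, sign: str | None = None) -> float:
    """Least-squares slope through the origin of J on w for one sign class.

    This is how the PSP coefficients (0.39 excitatory, 1.57 inhibitory
    per mV) are obtained from simulations with known connectivity:
    regress verified, correctly-signed couplings on the true PSPs.
    """
    w = np.asarray(w_true, dtype=float)
    j = np.asarray(j_fitted, dtype=float)
    if w.size != j.size:
        raise ValueError("w and J must have equal length")
    if w.size < 2:
        raise ValueError("need at least 2 verified pairs to calibrate")
    denom = float(np.sum(w * w))
    if denom == 0:
        raise ValueError("all true PSPs are zero")
    return float(np.sum(j * w) / denom)
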