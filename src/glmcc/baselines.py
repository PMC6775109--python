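"""Comparison detectors: the conventional cross-correlogram test and the
spike-jittering surrogate test.

Both operate on the 1-ms binned correlogram over [-50, +50] ms and look
for short-latency deviations on the causal side of the tested direction
(bins covering [1, 4] ms by default).

The conventional test assumes two independent stationary Poisson trains:
the expected count per bin is ``n_cc = lambda_pre lambda_post T delta``
and a bin outside ``n_cc +- z_alpha sqrt(n_cc)`` signals a connection.

The jitter test destroys millisecond timing while keeping slow structure
by perturbing every target spike uniformly in [-5, +5] ms, builds a
simultaneous (global) 99% acceptance band over the test-region bins
from the surrogate ensemble (max/min-statistic construction), and flags
a connection when the observed correlogram leaves the band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .correlogram import (BinnedCorrelogram, bin_correlogram,
                          collect_relative_times)

__all__ = ["BaselineDetection", "cc_method", "jitter_method"]

logger = logging.getLogger(__name__)

DEFAULT_TEST_REGION = (0.001, 0.004)  # s; causal short-lag search window


@dataclass
class BaselineDetection:
    """Outcome of a comparison detector for one direction of a pair."""

    method: str                 # "cc" | "jitter"
    verdict: str                # "excitatory" | "inhibitory" | "none"
    detecting_bins_ms: list     # lag bin starts (ms) outside the band
    band: tuple                 # (lower, upper) acceptance bounds used

    @property
    def detected(self) -> bool:
        return self.verdict != "none"


def _region_bins(hist: BinnedCorrelogram, region, side: int):
    lo, hi = region
    if side < 0:
        lo, hi = -hi, -lo
    starts = hist.edges[:-1]
    sel = (starts >= lo - 1e-12) & (starts + hist.delta <= hi + 1e-12)
    return np.flatnonzero(sel)


def cc_method(hist: BinnedCorrelogram, lam_pre: float, lam_post: float,
              T: float, alpha: float = 0.01, region=DEFAULT_TEST_REGION,
              side: int = +1, full_window: bool = False) -> BaselineDetection:
    """Poisson-band test on the binned correlogram.

    ``side=+1`` tests the causal direction reference -> target (positive
    lags); ``side=-1`` the reverse.  ``full_window=True`` scans every
    bin instead of the short-lag region.
    """
    delta = hist.delta
    n_cc = lam_pre * lam_post * T * delta
    if n_cc <= 0:
        logger.warning("cc_method: zero expected count, no test possible")
        return BaselineDetection("cc", "none", [], (np.nan, np.nan))
    z = norm.isf(alpha / 2.0)
    lower = n_cc - z * np.sqrt(n_cc)
    upper = n_cc + z * np.sqrt(n_cc)
    idx = (np.arange(hist.counts.size) if full_window
           else _region_bins(hist, region, side))
    counts = hist.counts[idx]
    above = counts > upper
    below = counts < lower
    det = []
    verdict = "none"
    if above.any() or below.any():
        # the strongest deviation decides the sign
        dev = np.where(above, counts - upper, np.where(below, lower - counts, 0))
        k = int(np.argmax(dev))
        verdict = "excitatory" if above[k] else "inhibitory"
        det = np.round(hist.edges[idx[above | below]] * 1e3, 9).tolist()
    return BaselineDetection("cc", verdict, det, (float(lower), float(upper)))


def jitter_method(trains, ref, tgt, jitter_half_width: float = 0.005,
                  n_surrogates: int = 1000, band_level: float = 0.99,
                  test_region=DEFAULT_TEST_REGION, delta: float = 0.001,
                  W: float = 0.05, seed: int | None = None,
                  side: int = +1) -> BaselineDetection:
    """Surrogate test with a simultaneous band over the test-region bins.

    Every *target* spike is jittered independently by
    Uniform(-jitter_half_width, +jitter_half_width) in each surrogate.
    The band is simultaneous over the region bins via the max-statistic
    construction: the upper bound is the 1-(1-band_level)/2 quantile of
    the per-surrogate maximum count, the lower bound the matching
    quantile of the minimum, so a null correlogram exits the band
    anywhere with probability ~(1 - band_level).  Detection requires
    the observed correlogram to leave the band in the region; the
    direction of the exit sets the verdict.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for a stable band")
    rng = np.random.default_rng(seed)
    rel = collect_relative_times(trains, ref, tgt, W=W)
    hist = bin_correlogram(rel, delta)
    idx = _region_bins(hist, test_region, side)
    obs = hist.counts[idx]
    region_lo = hist.edges[idx[0]] if idx.size else 0.0
    region_hi = hist.edges[idx[-1]] + delta if idx.size else 0.0

    tr = np.asarray(trains[ref], dtype=float)
    tt = np.asarray(trains[tgt], dtype=float)
    if tt.size == 0 or tr.size == 0 or idx.size == 0:
        return BaselineDetection("jitter", "none", [], (0.0, 0.0))

    # only (ref, tgt) pairs whose lag can reach the region after jitter
    # participate; precompute them once and jitter per target spike.
    margin = jitter_half_width + delta
    pair_lags = []
    pair_tgt_idx = []
    lo = np.searchsorted(tt, tr + region_lo - margin, side="left")
    hi = np.searchsorted(tt, tr + region_hi + margin, side="right")
    for r, (l, h) in zip(tr, zip(lo, hi)):
        if h > l:
            pair_lags.append(tt[l:h] - r)
            pair_tgt_idx.append(np.arange(l, h))
    if not pair_lags:
        return BaselineDetection("jitter", "none", [], (0.0, 0.0))
    lags = np.concatenate(pair_lags)
    tgt_idx = np.concatenate(pair_tgt_idx)
    uniq, inv = np.unique(tgt_idx, return_inverse=True)

    edges_lo = hist.edges[idx[0]]
    n_b = idx.size
    # surrogate counts: one uniform jitter per involved target spike
    jit = rng.uniform(-jitter_half_width, jitter_half_width,
                      size=(n_surrogates, uniq.size))
    shifted = lags[None, :] + jit[:, inv]
    bins = np.floor((shifted - edges_lo) / delta).astype(np.int64)
    ok = (bins >= 0) & (bins < n_b)
    rows = np.repeat(np.arange(n_surrogates), lags.size)[ok.ravel()]
    flat = rows * n_b + bins.ravel()[ok.ravel()]
    counts = np.bincount(flat, minlength=n_surrogates * n_b).reshape(
        n_surrogates, n_b)

    tail = (1.0 - band_level) / 2.0
    upper = float(np.quantile(counts.max(axis=1), 1.0 - tail,
                              method="higher"))
    lower = float(np.quantile(counts.min(axis=1), tail, method="lower"))
    above = obs > upper
    below = obs < lower
    verdict = "none"
    det = []
    if above.any() or below.any():
        dev = np.where(above, obs - upper, np.where(below, lower - obs, 0))
        k = int(np.argmax(dev))
        verdict = "excitatory" if above[k] else "inhibitory"
        det = np.round(hist.edges[idx[above | below]] * 1e3, 9).tolist()
    return BaselineDetection("jitter", verdict, det, (lower, upper))
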