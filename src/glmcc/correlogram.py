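"""Relative spike times (continuous cross-correlation data) and binned correlograms.

A cross-correlogram pools, over every spike of a reference neuron, the
times of target-neuron spikes measured relative to that spike.  The
pooled multiset of lags inside a window ``[-W, +W]`` is kept in
continuous time (:class:`RelativeSpikeTimes`); fitting works on these
lags directly, while the comparison detectors work on the 1-ms binned
histogram (:class:`BinnedCorrelogram`).

An optional *shadow* interval around zero lag excludes near-synchronous
spike pairs, which extracellular recordings lose because overlapping
waveforms cannot be sorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RelativeSpikeTimes",
    "BinnedCorrelogram",
    "collect_relative_times",
    "bin_correlogram",
]


@dataclass
class RelativeSpikeTimes:
    """Pooled lags of target spikes around reference spikes.

    Positive lag means the target fired *after* the reference.
    """

    lags: np.ndarray          # seconds, shadow < |lag| <= W
    W: float                  # window half-width, seconds
    shadow: float = 0.0       # excluded half-interval around 0, seconds
    n_ref: int = 0
    n_tgt: int = 0
    T: float = 0.0            # recording duration, seconds

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        if not self.W > 0:
            raise ValueError("window half-width W must be positive")
        if self.shadow < 0:
            raise ValueError("shadow must be non-negative")
        if self.lags.size:
            a = np.abs(self.lags)
            if a.max() > self.W + 1e-12:
                raise ValueError("lag outside [-W, W]")
            if self.shadow > 0 and a.min() <= self.shadow - 1e-12:
                raise ValueError("lag inside the shadow interval")

    @property
    def n(self) -> int:
        return int(self.lags.size)

    def mirrored(self) -> "RelativeSpikeTimes":
        """The same data seen from the other neuron (lags negated)."""
        return RelativeSpikeTimes(-self.lags, self.W, self.shadow,
                                  n_ref=self.n_tgt, n_tgt=self.n_ref, T=self.T)


@dataclass
class BinnedCorrelogram:
    """Histogram of lags over [-W, +W] at bin width delta (seconds)."""

    edges: np.ndarray   # n_bins + 1 edges, seconds
    counts: np.ndarray  # integer counts per bin

    @property
    def delta(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def flipped(self) -> "BinnedCorrelogram":
        """The correlogram of the reversed pair (lag sign negated)."""
        return BinnedCorrelogram(-self.edges[::-1].copy(), self.counts[::-1].copy())

    def to_frame(self) -> pd.DataFrame:
        """Bin centers (ms) and counts, the plotting/export layout."""
        return pd.DataFrame({"lag_ms": self.centers * 1e3, "count": self.counts})


def collect_relative_times(trains, ref, tgt, W: float = 0.05,
                           shadow: float = 0.0) -> RelativeSpikeTimes:
    """Pool target spike times relative to every reference spike.

    Returns all lags ``t_tgt - t_ref`` with ``shadow < |lag| <= W``.
    Positive lags mean the target fired after the reference.
    """
    if ref == tgt:
        raise ValueError("reference and target must be different neurons "
                         "(autocorrelograms are out of scope)")
    if not W > 0:
        raise ValueError("W must be positive")
    if shadow < 0:
        raise ValueError("shadow must be non-negative")
    tr = np.asarray(trains[ref], dtype=float)
    tt = np.asarray(trains[tgt], dtype=float)
    lags = _window_differences(tr, tt, W)
    if shadow > 0:
        lags = lags[np.abs(lags) > shadow]
    return RelativeSpikeTimes(lags, W, shadow, n_ref=tr.size, n_tgt=tt.size,
                              T=trains.T)


def _window_differences(ref: np.ndarray, tgt: np.ndarray, W: float) -> np.ndarray:
    """All pairwise differences tgt - ref with |diff| <= W (both sorted)."""
    if ref.size == 0 or tgt.size == 0:
        return np.empty(0)
    lo = np.searchsorted(tgt, ref - W, side="left")
    hi = np.searchsorted(tgt, ref + W, side="right")
    n_per = hi - lo
    total = int(n_per.sum())
    if total == 0:
        return np.empty(0)
    # gather via a flat index: for each ref spike i, tgt[lo[i]:hi[i]]
    rep_ref = np.repeat(ref, n_per)
    offsets = np.arange(total) - np.repeat(np.cumsum(n_per) - n_per, n_per)
    idx = np.repeat(lo, n_per) + offsets
    lags = tgt[idx] - rep_ref
    return lags[np.abs(lags) <= W]


def bin_correlogram(rel: RelativeSpikeTimes, delta: float = 0.001) -> BinnedCorrelogram:
    """Histogram the pooled lags with half-open bins [edge, edge+delta).

    ``delta`` must divide the full window ``2W``; a lag exactly at ``+W``
    is assigned to the last bin.
    """
    W = rel.W
    n_bins_f = 2 * W / delta
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin width {delta} does not divide the window 2W={2*W}")
    edges = -W + delta * np.arange(n_bins + 1)
    edges[-1] = W
    counts, _ = np.histogram(rel.lags, bins=edges)
    return BinnedCorrelogram(edges, counts)
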