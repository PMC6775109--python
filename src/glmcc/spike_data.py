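"""Spike-train containers, file I/O, firing rates and interspike-interval irregularity.

The universal input object is :class:`SpikeTrainSet`: a collection of
per-neuron spike-time arrays (seconds) together with the recording
interval ``[t_start, t_end)``.  All downstream analyses (correlograms,
connectivity fits, simulators) produce or consume this object.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "RateSummary",
    "read_spike_table",
    "write_spike_table",
    "read_res_clu",
    "firing_rates",
    "local_variation",
]

logger = logging.getLogger(__name__)


@dataclass
class SpikeTrainSet:
    """Parallel spike trains over a common recording interval.

    Parameters
    ----------
    spikes : dict
        Mapping from neuron id (any hashable label) to a 1-d array of
        spike times in seconds.  Times are sorted and de-duplicated on
        construction; exact duplicates within one neuron are collapsed
        to a single spike (and logged).
    t_start, t_end : float, optional
        Bounds of the recording interval in seconds.  Default to 0 and
        the maximum spike time.
    """

    spikes: dict
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self):
        cleaned = {}
        for nid, times in self.spikes.items():
            arr = np.asarray(times, dtype=float)
            arr = np.sort(arr)
            if arr.size:
                keep = np.concatenate(([True], np.diff(arr) > 0))
                n_dup = int(arr.size - keep.sum())
                if n_dup:
                    logger.info(
                        "neuron %r: collapsed %d duplicate spike time(s)", nid, n_dup
                    )
                arr = arr[keep]
            cleaned[nid] = arr
        self.spikes = cleaned
        if self.t_end is None:
            tmax = max((a[-1] for a in cleaned.values() if a.size), default=0.0)
            self.t_end = float(tmax)
        if not self.t_end > self.t_start:
            raise ValueError(
                f"recording interval must have positive duration, got "
                f"[{self.t_start}, {self.t_end})"
            )
        for nid, arr in self.spikes.items():
            if arr.size and (arr[0] < self.t_start or arr[-1] > self.t_end):
                raise ValueError(
                    f"neuron {nid!r} has spikes outside the recording interval"
                )

    @property
    def neuron_ids(self) -> list:
        return list(self.spikes.keys())

    @property
    def T(self) -> float:
        """Total recording duration in seconds."""
        return self.t_end - self.t_start

    def __len__(self) -> int:
        return len(self.spikes)

    def __getitem__(self, nid) -> np.ndarray:
        return self.spikes[nid]

    def counts(self) -> dict:
        return {nid: int(a.size) for nid, a in self.spikes.items()}

    def subset(self, neuron_ids) -> "SpikeTrainSet":
        return SpikeTrainSet(
            {nid: self.spikes[nid].copy() for nid in neuron_ids},
            t_start=self.t_start,
            t_end=self.t_end,
        )

    def restrict(self, t_start: float, t_end: float) -> "SpikeTrainSet":
        """Clip all trains to a sub-interval (new recording bounds)."""
        out = {
            nid: a[(a >= t_start) & (a < t_end)] for nid, a in self.spikes.items()
        }
        return SpikeTrainSet(out, t_start=t_start, t_end=t_end)


@dataclass
class RateSummary:
    """Per-neuron mean firing rates λ = N/T in Hz."""

    rates: dict = field(default_factory=dict)

    def __getitem__(self, nid) -> float:
        return self.rates[nid]

    def items(self):
        return self.rates.items()


def read_spike_table(path, dialect: str = "tsv", t_start: float = 0.0,
                     t_end: float | None = None) -> SpikeTrainSet:
    """Read a two-column spike table (neuron id, time in seconds).

    A header row with non-numeric second column is tolerated.  Malformed
    rows raise a parse error naming the offending line.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         names=["neuron_id", "time_s"], dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty spike table: {path}")
    if df.empty:
        raise ValueError(f"empty spike table: {path}")
    # optional header
    first = df.iloc[0]["time_s"]
    start_row = 0
    try:
        float(first)
    except (TypeError, ValueError):
        start_row = 1
        df = df.iloc[1:]
        if df.empty:
            raise ValueError(f"spike table has a header but no data rows: {path}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() | df["neuron_id"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + start_row + 1
        raise ValueError(f"malformed row at line {line} of {path}")
    spikes = {}
    for nid, grp in df.assign(time_s=times).groupby("neuron_id", sort=True):
        spikes[str(nid)] = grp["time_s"].to_numpy()
    return SpikeTrainSet(spikes, t_start=t_start, t_end=t_end)


def write_spike_table(trains: SpikeTrainSet, path, dialect: str = "tsv") -> None:
    """Write the TSV/CSV spike table that :func:`read_spike_table` reads."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    rows = []
    for nid in trains.neuron_ids:
        for t in trains[nid]:
            rows.append((nid, t))
    rows.sort(key=lambda r: (r[1], str(r[0])))
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    df.to_csv(path, sep=sep, header=False, index=False, float_format="%.9f")


def read_res_clu(res_path, clu_path, sampling_rate: float,
                 drop_clusters=(0, 1), t_start: float = 0.0,
                 t_end: float | None = None) -> SpikeTrainSet:
    """Read Klusters/CRCNS-style paired ``.res``/``.clu`` files.

    ``.res`` holds one integer sample index per spike; ``.clu`` holds a
    first line with the number of clusters followed by one cluster id
    per spike.  Times are ``sample_index / sampling_rate`` seconds.
    Clusters 0 and 1 (noise and artifact by convention) are dropped by
    default; the set is configurable via ``drop_clusters``.
    """
    def _read_ints(p):
        vals = []
        with open(p) as fh:
            for i, line in enumerate(fh, start=1):
                s = line.strip()
                if not s:
                    continue
                try:
                    vals.append(int(s))
                except ValueError:
                    raise ValueError(f"non-integer entry at line {i} of {p}")
        return np.asarray(vals, dtype=np.int64)

    res = _read_ints(res_path)
    clu = _read_ints(clu_path)
    if clu.size == 0:
        raise ValueError(f"empty .clu file: {clu_path}")
    clu = clu[1:]  # first line is the cluster count
    if res.size != clu.size:
        raise ValueError(
            f".res/.clu length mismatch: {res.size} spikes vs {clu.size} cluster ids"
        )
    keep = ~np.isin(clu, list(drop_clusters))
    if not keep.any():
        logger.warning("all spikes fell in dropped clusters %s", drop_clusters)
    spikes = {}
    for cid in np.unique(clu[keep]):
        spikes[str(int(cid))] = res[clu == cid] / float(sampling_rate)
    return SpikeTrainSet(spikes, t_start=t_start, t_end=t_end)


def firing_rates(trains: SpikeTrainSet) -> RateSummary:
    """Mean firing rate λ_i = N_i / T for every neuron, in Hz."""
    T = trains.T
    return RateSummary({nid: a.size / T for nid, a in trains.spikes.items()})


def local_variation(train) -> float:
    """Local variation (Lv) of the interspike intervals.

    Lv = (1/(n-1)) Σ_k 3 (I_k − I_{k+1})² / (I_k + I_{k+1})² over the n
    successive interspike intervals I_k.  Lv is 0 for perfectly regular
    firing and ≈1 for Poisson firing; it is invariant under rescaling
    time.  Returns NaN when fewer than 3 spikes (2 intervals) are
    available.
    """
    t = np.asarray(train, dtype=float)
    if t.size < 3:
        return math.nan
    iv = np.diff(t)
    s = iv[:-1] + iv[1:]
    d = iv[:-1] - iv[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, 3.0 * (d / np.where(s > 0, s, 1.0)) ** 2, 0.0)
    return float(terms.mean())
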