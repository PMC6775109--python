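"""Point-process generators with the statistical structure the model assumes.

Two generators live here: independent homogeneous Poisson trains (the
null fixture for calibrating the significance tests) and a coupled pair
whose conditional intensity is exactly the model's own generative form,

    lambda_2(t) = lambda_2 exp( J12 sum_k f(t - t_k^{(1)}) + m(t) ),

with the delayed exponential synaptic filter f and an optional shared
log-sinusoidal slow modulation m(t) emulating common background drive.
Sampling is exact Ogata thinning with a certified local intensity upper
bound, so the pooled lag histogram converges to the model intensity
shape.  The Hodgkin-Huxley network simulator lives in :mod:`glmcc.hh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import SynapticFilter
from .spike_data import SpikeTrainSet

__all__ = ["GlmPairConfig", "generate_independent_poisson", "generate_glm_pair"]


def generate_independent_poisson(rates, T: float, seed=None,
                                 t_start: float = 0.0) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains, one per entry of ``rates`` (Hz)."""
    rng = np.random.default_rng(seed)
    spikes = {}
    for k, lam in enumerate(rates):
        if lam < 0:
            raise ValueError("rates must be non-negative")
        n = rng.poisson(lam * T)
        spikes[str(k)] = np.sort(rng.uniform(t_start, t_start + T, size=n))
    return SpikeTrainSet(spikes, t_start=t_start, t_end=t_start + T)


@dataclass
class GlmPairConfig:
    """Settings for the coupled-pair generator.

    ``j12`` couples neuron 1 <- neuron 2's reference role: positive
    ``j12`` makes neuron 2 fire above baseline after each neuron-1
    spike.  ``mod_amplitude`` (log-rate units) and ``mod_period`` (s)
    add a shared sinusoidal baseline modulation to both neurons.
    """

    lam1: float = 10.0
    lam2: float = 10.0
    j12: float = 0.0
    j21: float = 0.0
    filter: SynapticFilter = field(
        default_factory=lambda: SynapticFilter(0.004, 0.001))
    T: float = 3600.0
    mod_amplitude: float = 0.0
    mod_period: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if not (self.lam1 > 0 and self.lam2 > 0 and self.T > 0):
            raise ValueError("rates and duration must be positive")


_MAX_EXPONENT = 30.0  # certified bound on J * (filter sum); beyond it the
                      # thinning envelope overflows and generation aborts


@njit(cache=True)
def _thinning_pair(T, lam1, lam2, j12, j21, tau, d, mod_amp, mod_period,
                   seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    cap1 = int(lam1 * np.exp(abs(j21) + mod_amp) * T * 1.5 + 1000)
    cap2 = int(lam2 * np.exp(abs(j12) + mod_amp) * T * 1.5 + 1000)
    t1 = np.empty(cap1)
    t2 = np.empty(cap2)
    n1 = 0
    n2 = 0
    p1 = 0  # next neuron-1 spike whose delayed filter has not activated
    p2 = 0
    s2 = 0.0  # sum of active filter terms driving neuron 2
    s1 = 0.0
    t = 0.0
    env = np.exp(mod_amp)
    two_pi = 2.0 * np.pi
    while t < T:
        # next pending filter activation limits the bound horizon
        h = T
        if p1 < n1 and t1[p1] + d < h:
            h = t1[p1] + d
        if p2 < n2 and t2[p2] + d < h:
            h = t2[p2] + d
        if h <= t:
            h = t
        # certified envelope on [t, h]: filter sums only decay there
        dec = np.exp(-(h - t) / tau) if h > t else 1.0
        e1 = max(j21 * s1, j21 * s1 * dec)
        e2 = max(j12 * s2, j12 * s2 * dec)
        if e1 > _MAX_EXPONENT or e2 > _MAX_EXPONENT:
            return t1[:0], t2[:0], 1  # envelope overflow: J too large
        bound1 = lam1 * np.exp(e1) * env
        bound2 = lam2 * np.exp(e2) * env
        B = bound1 + bound2
        dt = -np.log(np.random.random()) / B
        if t + dt > h:
            # advance to the activation (or the end) and absorb it
            if h >= T:
                break
            s1 = s1 * np.exp(-(h - t) / tau)
            s2 = s2 * np.exp(-(h - t) / tau)
            if p1 < n1 and t1[p1] + d <= h + 1e-15:
                s2 += 1.0
                p1 += 1
            if p2 < n2 and t2[p2] + d <= h + 1e-15:
                s1 += 1.0
                p2 += 1
            t = h
            continue
        s1 = s1 * np.exp(-dt / tau)
        s2 = s2 * np.exp(-dt / tau)
        t = t + dt
        mod = mod_amp * np.sin(two_pi * t / mod_period) if mod_amp != 0.0 else 0.0
        lam1_t = lam1 * np.exp(j21 * s1 + mod)
        lam2_t = lam2 * np.exp(j12 * s2 + mod)
        u = np.random.random() * B
        if u < lam1_t:
            if n1 >= cap1:
                return t1[:0], t2[:0], 2
            t1[n1] = t
            n1 += 1
        elif u < lam1_t + lam2_t:
            if n2 >= cap2:
                return t1[:0], t2[:0], 2
            t2[n2] = t
            n2 += 1
    return t1[:n1], t2[:n2], 0


def generate_glm_pair(config: GlmPairConfig) -> SpikeTrainSet:
    """Sample a coupled pair of spike trains from the generative model.

    Neuron "1" and neuron "2" interact through the delayed exponential
    filter with weights ``j12`` (1 drives 2) and ``j21`` (2 drives 1);
    either or both may be zero or negative.  Exact thinning; seed
    deterministic.
    """
    filt = config.filter
    if max(abs(config.j12), abs(config.j21)) > _MAX_EXPONENT:
        raise ValueError("coupling too strong: the thinning intensity "
                         "envelope would overflow; use a smaller |J|")
    seed = np.random.SeedSequence(config.seed).generate_state(1)[0] % (2 ** 31)
    t1, t2, status = _thinning_pair(
        config.T, config.lam1, config.lam2, config.j12, config.j21,
        filt.tau, filt.delay, config.mod_amplitude, config.mod_period,
        np.int64(seed))
    if status == 1:
        raise ValueError("coupling too strong: the thinning intensity "
                         "envelope overflowed; use a smaller |J|")
    if status == 2:
        raise RuntimeError("spike buffer overflow in pair generator")
    return SpikeTrainSet({"1": np.asarray(t1).copy(),
                          "2": np.asarray(t2).copy()},
                         t_start=0.0, t_end=config.T)
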