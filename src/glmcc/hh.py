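"""Conductance-based network simulator with known ground-truth connectivity.

A recurrent network of Hodgkin-Huxley-type neurons: regular-spiking
pyramidal cells (Na+, delayed-rectifier K+ and muscarinic M currents,
Traub-Miles-style kinetics) and fast-spiking interneurons (Erisir-type
Na+, Kv1.3 and Kv3.1-3.2 currents).  Excitatory synapses combine a
Tsodyks-Markram depressing AMPA conductance with a first-order NMDA
kinetic scheme under a voltage-dependent Mg2+ block; inhibitory
synapses are depressing GABA-A conductances.  Every neuron receives an
independent Ornstein-Uhlenbeck background conductance pair emulating
bombardment from unrecorded neurons.

AMPA peak conductances are log-normally distributed and NMDA/GABA
conductances normally distributed (negatives resampled); excitatory
cells innervate 12.5% and inhibitory cells 25% of the others.  The
ground-truth PSP matrix is obtained by a deterministic single-spike
probe of every connection: the postsynaptic cell is held at its mean
operating point (mean background conductances, noise off), one
presynaptic spike is delivered, and the peak signed deviation of the
membrane potential is recorded.

Integration uses exponential-Euler updates for both the gating
variables and the membrane potential (the currents are conductance
based, hence linear in V at fixed gating), with separate step sizes for
the two populations; spikes are detected as upward crossings of 0 mV
with a 2-ms hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .evaluation import GroundTruthNetwork
from .spike_data import SpikeTrainSet

__all__ = [
    "HHNetworkConfig",
    "simulate_hh_network",
    "measure_psp",
    "ou_conductance",
    "resting_state",
    "nmda_mg_block",
]

# --- fixed cellular / synaptic constants (units: mV, ms, mS/cm2, uF/cm2) ---

AREA_CM2 = 3.5e-4          # membrane area used to convert nS to mS/cm2
NS_TO_MSCM2 = 1e-6 / AREA_CM2

C_M = 1.0                  # both cell classes
# pyramidal (regular spiking with M current)
G_L_PYR, G_NA_PYR, G_K_PYR, G_M_PYR = 0.045, 50.0, 5.0, 0.07
E_L_PYR, E_NA_PYR, E_K_PYR = -80.0, 50.0, -90.0
V_T_PYR = -55.0            # kinetics shift of the Traub-Miles rate functions
TAU_MAX_M = 1000.0         # ms; M-current time-constant scale
# interneuron (Erisir fast spiking)
G_L_INH, G_NA_INH, G_K1_INH, G_K2_INH = 0.1, 112.0, 0.224, 224.0
E_L_INH, E_NA_INH, E_K_INH = -70.0, 55.0, -97.0
# synapses
E_AMPA, E_NMDA, E_GABA = 0.0, 0.0, -75.0
TAU_INA_AMPA, TAU_INA_GABA = 2.7, 10.0
TAU_REC = 500.0
U_AMPA, U_GABA = 0.25, 0.25
ALPHA_NMDA, BETA_NMDA = 0.5, 0.007
MG_MM = 1.0
PULSE_MS = 1.0             # transmitter pulse duration after each spike
# background OU conductances (nS)
G_E0_NS, G_I0_NS = 10.8, 51.3
SIG_E_NS, SIG_I_NS = 2.85, 6.26
TAU_E_MS, TAU_I_MS = 2.7, 10.5

SPIKE_THRESHOLD = 0.0      # mV, upward crossing
REARM_THRESHOLD = -30.0    # mV; the detector re-arms only after V falls
                           # below this, so depolarization-block plateaus
                           # are not counted as spike trains
REFRACTORY_MS = 2.0        # detection hold


def nmda_mg_block(v):
    """Voltage dependence of the NMDA conductance under 1 mM Mg2+."""
    return 1.0 / (1.0 + 0.28 * MG_MM * np.exp(-0.062 * np.asarray(v, float)))


@dataclass
class HHNetworkConfig:
    """Network composition, synaptic statistics and integration settings.

    Defaults follow the reference parameter set (Tables of cellular and
    synaptic constants above); the network size and duration default to
    a desk-scale configuration of 30 neurons for 30 s.  ``n_exc * p_exc`` etc.
    set the expected in-connectivity; negative sampled conductances are
    resampled.  Setting ``background_noise=False`` freezes the OU
    background at its mean; ``background_scale=0`` removes it.
    """

    n_exc: int = 24
    n_inh: int = 6
    duration: float = 30.0          # seconds
    p_exc: float = 0.125            # connection probability, E presynaptic
    p_inh: float = 0.25
    ampa_mu_log: float = -3.37      # natural log of mS/cm2
    ampa_sigma_log: float = 1.3
    nmda_mu: float = 8.5e-4         # mS/cm2
    nmda_sigma: float = 8.5e-5
    gaba_mu: float = 0.34           # mS/cm2
    gaba_sigma: float = 0.27
    delay_exc_ms: tuple = (0.0, 2.0)   # uniform range, AMPA & NMDA
    delay_inh_ms: tuple = (1.0, 3.0)   # uniform range, GABA
    dt_exc_ms: float = 0.01
    dt_inh_ms: float = 0.001
    background_noise: bool = True
    background_scale: float = 1.0
    # Desk-scale compensation: a small network lacks the recurrent drive
    # of its full-size counterpart, so the excitatory background (which
    # by construction represents input from unmodelled neurons) is
    # boosted per population.  Pyramidal cells are kept in the
    # fluctuation-driven regime (large sigma, near-threshold mean) and
    # interneurons in the mean-driven regime, reproducing the
    # high-rate/regular interneuron vs low-rate/irregular pyramid
    # structure of the full-scale network.
    bg_mean_mult_exc: float = 5.4
    bg_sigma_mult_exc: float = 7.5
    bg_mean_mult_inh: float = 3.0
    bg_sigma_mult_inh: float = 1.0
    bg_gi_mult_exc: float = 5.0
    bg_gi_mult_inh: float = 1.0
    # per-neuron lognormal jitter (sigma of log) of the excitatory
    # background mean: spreads cells over a continuum of excitability,
    # reproducing the skewed firing-rate distributions of large
    # networks and avoiding an all-or-none population threshold
    bg_hetero_exc: float = 0.0
    bg_hetero_inh: float = 0.0
    seed: int | None = None
    max_neurons: int = 80           # desk-scale guard
    max_duration: float = 600.0

    def validate(self):
        if self.n_exc + self.n_inh > self.max_neurons:
            raise ValueError(
                f"{self.n_exc + self.n_inh} neurons exceeds the desk-scale "
                f"guard ({self.max_neurons}); raise max_neurons explicitly "
                "for long-running configurations")
        if self.duration > self.max_duration:
            raise ValueError(
                f"duration {self.duration}s exceeds the desk-scale guard "
                f"({self.max_duration}s); raise max_duration explicitly")
        if not (0 <= self.p_exc <= 1 and 0 <= self.p_inh <= 1):
            raise ValueError("connection probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# rate functions (ms^-1); V in mV
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x / (exp(x/y) - 1), stable near x = 0
    r = x / y
    if abs(r) < 1e-7:
        return y * (1.0 - r / 2.0)
    return x / (math.exp(r) - 1.0)


@njit(cache=True)
def _pyr_rates(v):
    u = v - V_T_PYR
    am = 0.32 * _vtrap(13.0 - u, 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    ah = 0.128 * math.exp(-(u - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(u - 40.0) / 5.0))
    an = 0.032 * _vtrap(15.0 - u, 5.0)
    bn = 0.5 * math.exp(-(u - 10.0) / 40.0)
    # muscarinic M current, expressed as alpha/beta from p_inf and tau_p
    pinf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    taup = TAU_MAX_M / (3.3 * math.exp((v + 35.0) / 20.0)
                        + math.exp(-(v + 35.0) / 20.0))
    ap = pinf / taup
    bp = (1.0 - pinf) / taup
    return am, bm, ah, bh, an, bn, ap, bp


@njit(cache=True)
def _inh_rates(v):
    am = 40.0 * _vtrap(75.5 - v, 13.5)
    bm = 1.2262 * math.exp(-v / 42.248)
    ah = 0.0035 * math.exp(-v / 24.186)
    bh = 0.017 * _vtrap(-(v + 51.25), 5.2)
    an1 = 0.014 * _vtrap(-(v + 44.0), 2.3)       # Kv1.3
    bn1 = 0.0043 * math.exp(-(v + 44.0) / 34.0)
    an2 = _vtrap(95.0 - v, 11.8)                 # Kv3.1-3.2
    bn2 = 0.025 * math.exp(-v / 22.222)
    return am, bm, ah, bh, an1, bn1, an2, bn2


@njit(cache=True, inline="always")
def _gate_step(x, a, b, dt):
    tot = a + b
    if tot <= 0.0:
        return x
    xinf = a / tot
    return xinf + (x - xinf) * math.exp(-dt * tot)


@njit(cache=True)
def _pyr_step(v, m, h, n, p, g_syn_e, g_nmda_eff, g_syn_i, dt):
    am, bm, ah, bh, an, bn, ap, bp = _pyr_rates(v)
    m = _gate_step(m, am, bm, dt)
    h = _gate_step(h, ah, bh, dt)
    n = _gate_step(n, an, bn, dt)
    p = _gate_step(p, ap, bp, dt)
    g_na = G_NA_PYR * m * m * m * h
    g_k = G_K_PYR * n * n * n * n
    g_m = G_M_PYR * p
    g_tot = G_L_PYR + g_na + g_k + g_m + g_syn_e + g_nmda_eff + g_syn_i
    v_eff = (G_L_PYR * E_L_PYR + g_na * E_NA_PYR + (g_k + g_m) * E_K_PYR
             + (g_syn_e + g_nmda_eff) * E_AMPA + g_syn_i * E_GABA) / g_tot
    v = v_eff + (v - v_eff) * math.exp(-dt * g_tot / C_M)
    return v, m, h, n, p


@njit(cache=True)
def _inh_step(v, m, h, n1, n2, g_syn_e, g_nmda_eff, g_syn_i, dt):
    am, bm, ah, bh, an1, bn1, an2, bn2 = _inh_rates(v)
    m = _gate_step(m, am, bm, dt)
    h = _gate_step(h, ah, bh, dt)
    n1 = _gate_step(n1, an1, bn1, dt)
    n2 = _gate_step(n2, an2, bn2, dt)
    g_na = G_NA_INH * m * m * m * h
    g_k = G_K1_INH * n1 ** 4 + G_K2_INH * n2 * n2
    g_tot = G_L_INH + g_na + g_k + g_syn_e + g_nmda_eff + g_syn_i
    v_eff = (G_L_INH * E_L_INH + g_na * E_NA_INH + g_k * E_K_INH
             + (g_syn_e + g_nmda_eff) * E_AMPA + g_syn_i * E_GABA) / g_tot
    v = v_eff + (v - v_eff) * math.exp(-dt * g_tot / C_M)
    return v, m, h, n1, n2


@njit(cache=True)
def _settle(is_inh, g_e, g_i, settle_ms, dt):
    """Relax one neuron to its fixed point under constant conductances."""
    v = E_L_INH if is_inh else E_L_PYR
    x1 = x2 = x3 = x4 = 0.0
    if is_inh:
        am, bm, ah, bh, a3, b3, a4, b4 = _inh_rates(v)
    else:
        am, bm, ah, bh, a3, b3, a4, b4 = _pyr_rates(v)
    x1, x2 = am / (am + bm), ah / (ah + bh)
    x3, x4 = a3 / (a3 + b3), a4 / (a4 + b4)
    n_steps = int(settle_ms / dt)
    for _ in range(n_steps):
        if is_inh:
            v, x1, x2, x3, x4 = _inh_step(v, x1, x2, x3, x4, g_e, 0.0, g_i, dt)
        else:
            v, x1, x2, x3, x4 = _pyr_step(v, x1, x2, x3, x4, g_e, 0.0, g_i, dt)
    return v, x1, x2, x3, x4


@njit(cache=True)
def _control_trace(is_inh, g_bg_e, g_bg_i, dt, n_steps):
    """Membrane trajectory with no synaptic input (drift reference)."""
    v, x1, x2, x3, x4 = _settle(is_inh, g_bg_e, g_bg_i, 2000.0, dt)
    out = np.empty(n_steps)
    for s in range(n_steps):
        if is_inh:
            v, x1, x2, x3, x4 = _inh_step(v, x1, x2, x3, x4, g_bg_e, 0.0,
                                          g_bg_i, dt)
        else:
            v, x1, x2, x3, x4 = _pyr_step(v, x1, x2, x3, x4, g_bg_e, 0.0,
                                          g_bg_i, dt)
        out[s] = v
    return out


@njit(cache=True)
def _probe_batch(g1, g2, is_gaba, post_inh, g_bg_e, g_bg_i, dt, probe_ms):
    """Peak signed membrane deflection after one presynaptic spike.

    g1: AMPA (or GABA) peak conductance; g2: NMDA (0 for GABA).
    The postsynaptic cell starts from its settled operating point under
    the constant background conductances (g_bg_e, g_bg_i); residual
    settling drift is removed by referencing an input-free control
    trajectory.
    """
    out = np.empty(g1.size)
    n_steps = int(probe_ms / dt)
    pulse_steps = int(PULSE_MS / dt)
    # settle the two cell types once each, plus drift controls
    vp, p1, p2, p3, p4 = _settle(False, g_bg_e, g_bg_i, 2000.0, dt)
    vi, q1, q2, q3, q4 = _settle(True, g_bg_e, g_bg_i, 2000.0, dt)
    ctrl_p = _control_trace(False, g_bg_e, g_bg_i, dt, n_steps)
    ctrl_i = _control_trace(True, g_bg_e, g_bg_i, dt, n_steps)
    for k in range(g1.size):
        inh = post_inh[k]
        if inh:
            v, x1, x2, x3, x4 = vi, q1, q2, q3, q4
        else:
            v, x1, x2, x3, x4 = vp, p1, p2, p3, p4
        if is_gaba[k]:
            g_fast = g1[k] * U_GABA
            tau_fast = TAU_INA_GABA
            gn = 0.0
        else:
            g_fast = g1[k] * U_AMPA
            tau_fast = TAU_INA_AMPA
            gn = g2[k]
        r_n = 0.0
        peak = 0.0
        dec_fast = math.exp(-dt / tau_fast)
        rinf = ALPHA_NMDA / (ALPHA_NMDA + BETA_NMDA)
        dec_pulse = math.exp(-dt * (ALPHA_NMDA + BETA_NMDA))
        dec_n = math.exp(-dt * BETA_NMDA)
        for s in range(n_steps):
            if s < pulse_steps:
                r_n = rinf + (r_n - rinf) * dec_pulse
            else:
                r_n *= dec_n
            fmg = 1.0 / (1.0 + 0.28 * MG_MM * math.exp(-0.062 * v))
            g_nmda_eff = gn * r_n * fmg
            if is_gaba[k]:
                ge_s, gi_s = g_bg_e, g_bg_i + g_fast
            else:
                ge_s, gi_s = g_bg_e + g_fast, g_bg_i
            if inh:
                v, x1, x2, x3, x4 = _inh_step(v, x1, x2, x3, x4, ge_s,
                                              g_nmda_eff, gi_s, dt)
            else:
                v, x1, x2, x3, x4 = _pyr_step(v, x1, x2, x3, x4, ge_s,
                                              g_nmda_eff, gi_s, dt)
            g_fast *= dec_fast
            dev = v - (ctrl_i[s] if inh else ctrl_p[s])
            if abs(dev) > abs(peak):
                peak = dev
        out[k] = peak
    return out


@njit(cache=True)
def _run_network(n, is_inh, pre_ptr, post_idx, g_fast, g_nmda, delay_steps,
                 nmda_delay_steps, duration_ms, dt_e, n_sub,
                 g_e0_arr, g_i0_arr, sig_e_arr, sig_i_arr, tau_e, tau_i,
                 noise_on, v0, gate0, seed, max_spikes):
    np.random.seed(seed)
    dt_i = dt_e / n_sub
    n_steps = int(duration_ms / dt_e)
    L = 0
    for k in range(delay_steps.size):
        if delay_steps[k] + 2 > L:
            L = delay_steps[k] + 2
    for k in range(nmda_delay_steps.size):
        if nmda_delay_steps[k] + 2 > L:
            L = nmda_delay_steps[k] + 2
    if L < 4:
        L = 4
    jump_a = np.zeros((L, n))
    jump_g = np.zeros((L, n))
    nmda_start = np.zeros((L, n), dtype=np.int8)

    V = v0.copy()
    gates = gate0.copy()
    G_a = np.zeros(n)       # summed AMPA conductance onto each neuron
    G_g = np.zeros(n)       # summed GABA conductance
    R_n = np.zeros(n)       # summed gN_ij * r_j onto each neuron
    w_syn = np.zeros(n)     # Tsodyks effective resource, per presyn
    r_syn = np.ones(n)      # Tsodyks recovered resource, per presyn
    r_nmda = np.zeros(n)    # NMDA open fraction, per presyn
    pulse_left = np.zeros(n, dtype=np.int64)
    g_e = g_e0_arr.copy()
    g_i = g_i0_arr.copy()
    last_spike = np.full(n, -1e9)
    armed = np.ones(n, dtype=np.int8)

    dec_a = math.exp(-dt_e / TAU_INA_AMPA)
    dec_g = math.exp(-dt_e / TAU_INA_GABA)
    f_rec = 1.0 - math.exp(-dt_e / TAU_REC)
    dec_n = math.exp(-dt_e * BETA_NMDA)
    rinf_n = ALPHA_NMDA / (ALPHA_NMDA + BETA_NMDA)
    dec_pulse = math.exp(-dt_e * (ALPHA_NMDA + BETA_NMDA))
    pulse_steps = int(PULSE_MS / dt_e)
    ou_ae = math.exp(-dt_e / tau_e)
    ou_ai = math.exp(-dt_e / tau_i)
    ou_be = np.sqrt(1.0 - ou_ae * ou_ae) * sig_e_arr
    ou_bi = np.sqrt(1.0 - ou_ai * ou_ai) * sig_i_arr

    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    spike_time = np.empty(max_spikes)
    n_spk = 0

    for step in range(n_steps):
        t_ms = step * dt_e
        row = step % L
        # scheduled arrivals
        for i in range(n):
            if jump_a[row, i] != 0.0:
                G_a[i] += jump_a[row, i]
                jump_a[row, i] = 0.0
            if jump_g[row, i] != 0.0:
                G_g[i] += jump_g[row, i]
                jump_g[row, i] = 0.0
            if nmda_start[row, i] != 0:
                pulse_left[i] = pulse_steps
                nmda_start[row, i] = 0
        # NMDA open fractions: global decay plus pulse-driven corrections
        for i in range(n):
            R_n[i] *= dec_n
        for j in range(n):
            if is_inh[j]:
                continue
            if pulse_left[j] > 0:
                r_old = r_nmda[j]
                r_new = rinf_n + (r_old - rinf_n) * dec_pulse
                r_nmda[j] = r_new
                pulse_left[j] -= 1
                dr = r_new - r_old * dec_n
                for kk in range(pre_ptr[j], pre_ptr[j + 1]):
                    R_n[post_idx[kk]] += g_nmda[kk] * dr
            else:
                r_nmda[j] *= dec_n
        # Tsodyks resources (per presynaptic neuron)
        for j in range(n):
            r_syn[j] += (1.0 - r_syn[j] - w_syn[j]) * f_rec
            w_syn[j] *= dec_g if is_inh[j] else dec_a
        # background conductances
        if noise_on:
            for i in range(n):
                g_e[i] = (g_e0_arr[i] + (g_e[i] - g_e0_arr[i]) * ou_ae
                          + ou_be[i] * np.random.normal())
                g_i[i] = (g_i0_arr[i] + (g_i[i] - g_i0_arr[i]) * ou_ai
                          + ou_bi[i] * np.random.normal())
                if g_e[i] < 0.0:
                    g_e[i] = 0.0
                if g_i[i] < 0.0:
                    g_i[i] = 0.0
        # membrane updates
        for i in range(n):
            v_prev = V[i]
            fmg = 1.0 / (1.0 + 0.28 * MG_MM * math.exp(-0.062 * V[i]))
            g_nmda_eff = R_n[i] * fmg
            ge_s = G_a[i] + g_e[i]
            gi_s = G_g[i] + g_i[i]
            if is_inh[i]:
                v = V[i]
                x1, x2, x3, x4 = gates[i, 0], gates[i, 1], gates[i, 2], gates[i, 3]
                for _ in range(n_sub):
                    v, x1, x2, x3, x4 = _inh_step(v, x1, x2, x3, x4, ge_s,
                                                  g_nmda_eff, gi_s, dt_i)
                V[i] = v
                gates[i, 0], gates[i, 1], gates[i, 2], gates[i, 3] = x1, x2, x3, x4
            else:
                v, x1, x2, x3, x4 = _pyr_step(
                    V[i], gates[i, 0], gates[i, 1], gates[i, 2], gates[i, 3],
                    ge_s, g_nmda_eff, gi_s, dt_e)
                V[i] = v
                gates[i, 0], gates[i, 1], gates[i, 2], gates[i, 3] = x1, x2, x3, x4
            if abs(V[i]) > 200.0:
                return spike_neuron[:n_spk], spike_time[:n_spk], 1
            # spike detection (with hysteresis) and synaptic release
            if armed[i] == 0 and V[i] < REARM_THRESHOLD:
                armed[i] = 1
            if (armed[i] == 1 and v_prev <= SPIKE_THRESHOLD
                    and V[i] > SPIKE_THRESHOLD
                    and t_ms - last_spike[i] >= REFRACTORY_MS):
                armed[i] = 0
                last_spike[i] = t_ms
                if n_spk >= max_spikes:
                    return spike_neuron[:n_spk], spike_time[:n_spk], 2
                spike_neuron[n_spk] = i
                spike_time[n_spk] = t_ms
                n_spk += 1
                release = (U_GABA if is_inh[i] else U_AMPA) * r_syn[i]
                w_syn[i] += release
                r_syn[i] -= release  # resource transfer (Tsodyks-Markram)
                for kk in range(pre_ptr[i], pre_ptr[i + 1]):
                    tgt = post_idx[kk]
                    arr = (step + delay_steps[kk]) % L
                    if is_inh[i]:
                        jump_g[arr, tgt] += g_fast[kk] * release
                    else:
                        jump_a[arr, tgt] += g_fast[kk] * release
                if not is_inh[i]:
                    arr = (step + nmda_delay_steps[i]) % L
                    nmda_start[arr, i] = 1
    return spike_neuron[:n_spk], spike_time[:n_spk], 0


# ---------------------------------------------------------------------------
# public interface
# ---------------------------------------------------------------------------

def ou_conductance(g0: float, sigma: float, tau_ms: float, duration_ms: float,
                   dt_ms: float = 0.01, seed=None) -> np.ndarray:
    """Sample path of the Ornstein-Uhlenbeck background conductance.

    Exact discretization of dg = -(g - g0)/tau dt + sqrt(2 sigma^2/tau)
    xi(t) dt; the stationary law is Normal(g0, sigma^2).  Units follow
    the inputs (nS in the network's tables).
    """
    from scipy.signal import lfilter
    rng = np.random.default_rng(seed)
    n = int(duration_ms / dt_ms)
    a = math.exp(-dt_ms / tau_ms)
    b = sigma * math.sqrt(1.0 - a * a)
    noise = rng.standard_normal(n) * b
    dev = lfilter([1.0], [1.0, -a], noise)
    return g0 + dev


def resting_state(cell_type: str = "excitatory", background: bool = False,
                  background_scale: float = 1.0, dt_ms: float = 0.01,
                  settle_ms: float = 2000.0):
    """Settled membrane potential (mV) of an isolated neuron.

    With ``background=False`` all inputs are absent and the cell relaxes
    to its leak-dominated rest; with ``background=True`` the OU
    background is frozen at its mean, giving the in-network operating
    point.
    """
    inh = cell_type == "inhibitory"
    if background:
        ge = G_E0_NS * NS_TO_MSCM2 * background_scale
        gi = G_I0_NS * NS_TO_MSCM2 * background_scale
    else:
        ge = gi = 0.0
    v, *_ = _settle(inh, ge, gi, settle_ms, dt_ms)
    return float(v)


def measure_psp(conductance, receptor: str = "AMPA+NMDA",
                cell_type: str = "excitatory", nmda_conductance: float = 0.0,
                background: bool = True, dt_ms: float = 0.01,
                probe_ms: float = 200.0) -> float:
    """Deterministic single-spike PSP probe (mV, signed).

    One presynaptic spike is delivered to a quiescent postsynaptic cell
    of the given type held at its operating point (mean background
    conductances, noise off; ``background=False`` probes from the bare
    resting potential).  ``receptor`` selects "AMPA+NMDA" (excitatory,
    ``conductance`` = AMPA peak, plus optional ``nmda_conductance``) or
    "GABA".  The PSP is the peak signed deviation of V from rest.  A
    zero conductance returns exactly 0; negative conductances are
    rejected.
    """
    if conductance < 0:
        raise ValueError("conductance must be non-negative")
    if conductance == 0 and nmda_conductance == 0:
        return 0.0
    if receptor not in ("AMPA+NMDA", "GABA"):
        raise ValueError(f"unknown receptor class {receptor!r}")
    ge = G_E0_NS * NS_TO_MSCM2 if background else 0.0
    gi = G_I0_NS * NS_TO_MSCM2 if background else 0.0
    out = _probe_batch(np.array([float(conductance)]),
                       np.array([float(nmda_conductance)]),
                       np.array([receptor == "GABA"]),
                       np.array([cell_type == "inhibitory"]),
                       ge, gi, dt_ms, probe_ms)
    return float(out[0])


def _sample_positive(rng, mu, sigma, size):
    out = rng.normal(mu, sigma, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = out < 0
    return out


def simulate_hh_network(config: HHNetworkConfig | None = None, **overrides):
    """Simulate the recurrent network; returns (spike trains, ground truth).

    The ground-truth PSP matrix ``truth.w[i, j]`` holds the probed PSP
    of the connection j -> i in mV (0 when unconnected).
    """
    if config is None:
        config = HHNetworkConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides")
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_exc + config.n_inh
    is_inh = np.zeros(n, dtype=np.bool_)
    is_inh[config.n_exc:] = True

    # wiring: CSR over presynaptic neurons
    pre_ptr = np.zeros(n + 1, dtype=np.int64)
    post_lists, gf_lists, gn_lists, d_lists = [], [], [], []
    dt_e = config.dt_exc_ms
    for j in range(n):
        others = np.array([i for i in range(n) if i != j])
        p = config.p_inh if is_inh[j] else config.p_exc
        sel = others[rng.random(others.size) < p]
        post_lists.append(sel)
        m = sel.size
        if is_inh[j]:
            gf_lists.append(_sample_positive(rng, config.gaba_mu,
                                             config.gaba_sigma, m))
            gn_lists.append(np.zeros(m))
            d_lists.append(rng.uniform(*config.delay_inh_ms, m))
        else:
            gf_lists.append(np.exp(rng.normal(config.ampa_mu_log,
                                              config.ampa_sigma_log, m)))
            gn_lists.append(_sample_positive(rng, config.nmda_mu,
                                             config.nmda_sigma, m))
            d_lists.append(rng.uniform(*config.delay_exc_ms, m))
        pre_ptr[j + 1] = pre_ptr[j] + m
    post_idx = np.concatenate(post_lists) if n else np.empty(0, dtype=np.int64)
    g_fast = np.concatenate(gf_lists)
    g_nmda = np.concatenate(gn_lists)
    delays = np.concatenate(d_lists)
    delay_steps = np.maximum(1, np.round(delays / dt_e)).astype(np.int64)
    nmda_delay = rng.uniform(*config.delay_exc_ms, n)
    nmda_delay_steps = np.maximum(1, np.round(nmda_delay / dt_e)).astype(np.int64)

    # per-neuron background statistics (desk-scale compensation applied
    # to the excitatory background channel)
    bg = config.background_scale
    mean_mult = np.where(is_inh, config.bg_mean_mult_inh,
                         config.bg_mean_mult_exc)
    hetero = np.where(is_inh, config.bg_hetero_inh, config.bg_hetero_exc)
    mean_mult = mean_mult * np.exp(rng.normal(0.0, 1.0, n) * hetero)
    sig_mult = np.where(is_inh, config.bg_sigma_mult_inh,
                        config.bg_sigma_mult_exc)
    gi_mult = np.where(is_inh, config.bg_gi_mult_inh, config.bg_gi_mult_exc)
    ge0_arr = G_E0_NS * NS_TO_MSCM2 * bg * mean_mult
    gi0_arr = G_I0_NS * NS_TO_MSCM2 * bg * gi_mult
    sig_e_arr = SIG_E_NS * NS_TO_MSCM2 * bg * sig_mult
    sig_i_arr = SIG_I_NS * NS_TO_MSCM2 * bg * sig_mult

    # initial conditions: settled at the mean operating point
    v0 = np.empty(n)
    gate0 = np.empty((n, 4))
    for i in range(n):
        st = _settle(bool(is_inh[i]), ge0_arr[i], gi0_arr[i], 2000.0, dt_e)
        v0[i] = st[0]
        gate0[i] = st[1:]

    n_sub = max(1, int(round(config.dt_exc_ms / config.dt_inh_ms)))
    max_spikes = int(n * config.duration * 200) + 10000
    seed = int(np.random.SeedSequence(config.seed).generate_state(2)[1] % (2 ** 31))
    noise_on = config.background_noise and bg > 0
    if not noise_on:
        sig_e_arr = np.zeros(n)
        sig_i_arr = np.zeros(n)
    spk_n, spk_t, status = _run_network(
        n, is_inh.astype(np.int8), pre_ptr, post_idx, g_fast, g_nmda,
        delay_steps, nmda_delay_steps, config.duration * 1e3, dt_e, n_sub,
        ge0_arr, gi0_arr, sig_e_arr, sig_i_arr,
        TAU_E_MS, TAU_I_MS, noise_on, v0, gate0, seed, max_spikes)
    if status == 1:
        raise RuntimeError("numerical blow-up: |V| exceeded 200 mV")
    if status == 2:
        raise RuntimeError("spike buffer overflow; network is runaway-active")

    ids = [f"e{i}" if not is_inh[i] else f"i{i}" for i in range(n)]
    spikes = {nid: [] for nid in ids}
    for neuron, t in zip(np.asarray(spk_n), np.asarray(spk_t)):
        spikes[ids[int(neuron)]].append(t * 1e-3)
    trains = SpikeTrainSet({k: np.array(v) for k, v in spikes.items()},
                           t_start=0.0, t_end=config.duration)

    # ground truth via the deterministic probe at the nominal (mean
    # background) operating point; the desk-scale drive boost is a
    # property of the activity regime, not of the synapses, so it does
    # not enter the PSP definition
    w = np.zeros((n, n))
    if post_idx.size:
        pre_of = _presyn_of(pre_ptr, n)
        probe = _probe_batch(g_fast, g_nmda, is_inh[pre_of],
                             is_inh[post_idx],
                             G_E0_NS * NS_TO_MSCM2 * bg,
                             G_I0_NS * NS_TO_MSCM2 * bg, dt_e, 200.0)
        for k in range(post_idx.size):
            w[post_idx[k], pre_of[k]] = probe[k]
    cell_types = {ids[i]: ("inhibitory" if is_inh[i] else "excitatory")
                  for i in range(n)}
    truth = GroundTruthNetwork(ids, w, cell_types)
    return trains, truth


def _presyn_of(pre_ptr, n):
    counts = np.diff(pre_ptr)
    return np.repeat(np.arange(n), counts)
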