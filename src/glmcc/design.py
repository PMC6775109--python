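"""Closed-form experiment design: how long must one record to verify a synapse?

Under the null hypothesis of independent stationary firing, the
confidence bound on the coupling parameter depends only on the recording
duration T and the firing rates of the two neurons,

    J_pm = +- c / sqrt(T tau lambda_pre lambda_post),   c = 1.57 z_alpha.

With the calibrated proportionality J = a w between the coupling and the
postsynaptic potential w (a = 0.39 excitatory, 1.57 inhibitory), a
connection of presumed size w becomes verifiable once

    T > c^2 / (tau lambda_pre lambda_post a^2 w^2)

and, additionally, once enough coincidences have accumulated in the
interaction window:

    T lambda_pre lambda_post > 10 / tau.

The larger of the two bounds is the required duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .inference import DETECTABILITY_PREFACTOR, PSP_COEFF_EXC, PSP_COEFF_INH

__all__ = [
    "DurationRequirement",
    "confidence_bound_J",
    "required_duration",
    "duration_table",
    "format_duration",
]

MIN_PAIR_COINCIDENCES = 10.0  # pooled-count floor in the tau window


@dataclass
class DurationRequirement:
    """Required recording duration for one rate/PSP scenario (seconds)."""

    lam_pre: float
    lam_post: float
    w_mV: float        # signed presumed PSP
    alpha: float
    tau: float
    c: float           # 1.57 z_alpha
    a: float           # PSP coefficient for the sign class
    T_psp: float       # detectability bound, s
    T_count: float     # coincidence-count bound, s
    T_required: float  # max of the two, s

    @property
    def human(self) -> str:
        return format_duration(self.T_required)


def confidence_bound_J(T: float, lam_pre: float, lam_post: float,
                       tau: float, alpha: float) -> float:
    """Half-width of the null confidence interval on J (the +- bound)."""
    if min(T, lam_pre, lam_post, tau) <= 0:
        raise ValueError("T, rates and tau must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    c = DETECTABILITY_PREFACTOR * norm.isf(alpha / 2.0)
    return c / math.sqrt(T * tau * lam_pre * lam_post)


def required_duration(lam_pre: float, lam_post: float, w_mV: float,
                      sign: str | None = None, alpha: float = 0.001,
                      tau: float = 0.001) -> DurationRequirement:
    """Recording duration needed to verify a PSP of presumed size ``w_mV``.

    ``sign`` is "excitatory"/"inhibitory" (or "e"/"i"); if omitted it is
    inferred from the sign of ``w_mV``.
    """
    if w_mV == 0:
        raise ValueError("a zero PSP is undetectable at any duration")
    if min(lam_pre, lam_post, tau) <= 0:
        raise ValueError("rates and tau must be positive")
    if sign is None:
        sign = "excitatory" if w_mV > 0 else "inhibitory"
    sign = {"e": "excitatory", "i": "inhibitory"}.get(sign, sign)
    a = PSP_COEFF_EXC if sign == "excitatory" else PSP_COEFF_INH
    c = DETECTABILITY_PREFACTOR * norm.isf(alpha / 2.0)
    rate_prod = lam_pre * lam_post
    T_psp = c ** 2 / (tau * rate_prod * a ** 2 * w_mV ** 2)
    T_count = MIN_PAIR_COINCIDENCES / (tau * rate_prod)
    return DurationRequirement(lam_pre, lam_post, w_mV, alpha, tau, c, a,
                               T_psp, T_count, max(T_psp, T_count))


def _round_1sf(x: float) -> float:
    if x <= 0:
        return 0.0
    p = 10.0 ** math.floor(math.log10(x))
    return round(x / p) * p


def format_duration(T_seconds: float) -> str:
    """Human-readable requirement: minutes below an hour, else hours,
    rounded to one significant figure (e.g. 29.2 min -> "30 min",
    58.4 min -> "1 h", 194.5 h -> "200 h")."""
    minutes = T_seconds / 60.0
    if minutes < 60.0:
        r = _round_1sf(minutes)
        if r < 60.0:
            return f"{r:g} min"
    hours = minutes / 60.0
    return f"{_round_1sf(hours):g} h"


DEFAULT_RATE_PAIRS = [(10, 10), (10, 5), (5, 5), (10, 1), (5, 1), (1, 1)]
DEFAULT_PSP_SPECS = [("EPSP", 5.0), ("EPSP", 1.0), ("EPSP", 0.5),
                     ("IPSP", 1.0), ("IPSP", 0.5)]


def duration_table(rate_pairs=None, psp_specs=None, alpha: float = 0.001,
                   tau: float = 0.001) -> pd.DataFrame:
    """Required-duration table over firing-rate pairs and presumed PSPs.

    Rows are (lambda_pre, lambda_post) pairs in Hz, columns the PSP
    scenarios; cells hold the one-significant-figure human-readable
    requirement.  The defaults cover the standard grid of rate pairs
    from (10, 10) down to (1, 1) Hz and PSPs of 5/1/0.5 mV.
    """
    if rate_pairs is None:
        rate_pairs = DEFAULT_RATE_PAIRS
    if psp_specs is None:
        psp_specs = DEFAULT_PSP_SPECS
    cols = [f"{kind}: {w:g} mV" for kind, w in psp_specs]
    rows = {}
    for pre, post in rate_pairs:
        cells = []
        for kind, w in psp_specs:
            sign = "excitatory" if kind.upper().startswith("E") else "inhibitory"
            wm = w if sign == "excitatory" else -w
            req = required_duration(pre, post, wm, sign, alpha=alpha, tau=tau)
            cells.append(f"T > {req.human}")
        rows[f"({pre:g}, {post:g}) Hz"] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
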