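"""Effect-size and probability conversions.

Rate <-> probability (p = 1 - e^(-rt)), odds-ratio -> relative-risk (Zhang-Yu),
hazard-ratio application on the rate scale, per-cycle discount factors, and the
derivation of the usual-care A-D transition matrix from the intervention-arm
matrix by deflating transitions into the effectiveness factor's target states.

All functions broadcast over numpy arrays so the PSA can apply them to whole
draw batches at once.
"""

from __future__ import annotations

import numpy as np

CHRONIC_NAMES = ("A", "B", "C", "D")

__all__ = [
    "rate_to_prob",
    "prob_to_rate",
    "or_to_rr",
    "apply_hazard_ratio",
    "cycle_discount_factor",
    "derive_uc_transitions",
]


def rate_to_prob(rate, t: float = 1.0):
    """Convert an event rate over duration ``t`` to a probability, p = 1 - e^(-rt)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    if t <= 0:
        raise ValueError("duration must be > 0")
    out = -np.expm1(-rate * t)
    return float(out) if out.ndim == 0 else out


def prob_to_rate(p, t: float = 1.0):
    """Inverse of :func:`rate_to_prob`: r = -ln(1 - p) / t."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability must lie in [0, 1]")
    if np.any(p == 1):
        raise ValueError("p = 1 corresponds to an infinite rate")
    if t <= 0:
        raise ValueError("duration must be > 0")
    out = -np.log1p(-p) / t
    return float(out) if out.ndim == 0 else out


def or_to_rr(odds_ratio, p0):
    """Convert an odds ratio to a relative risk at reference risk ``p0``.

    Uses the Zhang-Yu correction RR = OR / (1 - p0 + p0 * OR); the result
    always lies between min(1, OR) and max(1, OR).
    """
    odds_ratio = np.asarray(odds_ratio, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if np.any(odds_ratio <= 0):
        raise ValueError("odds ratio must be > 0")
    if np.any((p0 < 0) | (p0 >= 1)):
        raise ValueError("reference risk must lie in [0, 1)")
    out = odds_ratio / (1.0 - p0 + p0 * odds_ratio)
    return float(out) if out.ndim == 0 else out


def apply_hazard_ratio(p, hr):
    """Apply a hazard ratio to a probability on the rate scale.

    p' = 1 - (1 - p)^hr, i.e. r' = hr * r with r = -ln(1 - p).
    """
    p = np.asarray(p, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("probability must lie in [0, 1)")
    if np.any(hr <= 0):
        raise ValueError("hazard ratio must be > 0")
    out = -np.expm1(hr * np.log1p(-p))
    return float(out) if out.ndim == 0 else out


def cycle_discount_factor(annual_rate: float, cycle):
    """Discount factor (1 + d)^(-t/12) for monthly cycle index ``t``."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    cycle = np.asarray(cycle, dtype=float)
    out = (1.0 + annual_rate) ** (-cycle / 12.0)
    return float(out) if out.ndim == 0 else out


def derive_uc_transitions(base, odds_ratio, target_states,
                          mode: str = "zhang_yu_rr",
                          fixed_reference_risk: float | None = None,
                          strict: bool = True):
    """Derive the usual-care A-D matrix from the intervention-arm matrix.

    Each transition from an origin outside ``target_states`` into a state
    inside ``target_states`` is deflated; the removed mass is returned to the
    origin's self-loop, so rows stay stochastic.

    Parameters
    ----------
    base:
        Row-stochastic matrix of shape ``(..., 4, 4)`` over states A-D
        (self-loops on the diagonal), for the intervention arm. Leading axes
        broadcast (PSA draw batches).
    odds_ratio:
        Scalar or array broadcastable against the leading axes of ``base``.
    target_states:
        Iterable of state letters the factor promotes, e.g. ``("A", "B")``.
    mode:
        ``"zhang_yu_rr"`` divides each cell by RR = or_to_rr(OR, p0) with p0
        the intervention-arm cell itself (or ``fixed_reference_risk``);
        ``"exact_odds"`` divides the cell's odds by OR.
    strict:
        When True (default) any resulting entry outside [0, 1] raises; when
        False the unclipped matrix is returned and the caller is responsible
        for rejecting invalid rows (used by the PSA's redraw loop).
    """
    base = np.asarray(base, dtype=float)
    if base.shape[-2:] != (4, 4):
        raise ValueError("base must have shape (..., 4, 4)")
    if np.any(np.abs(base.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError("base rows must sum to 1")
    targets = set(target_states)
    if not targets or not targets <= set(CHRONIC_NAMES):
        raise ValueError(f"invalid target states: {target_states}")
    if mode not in ("zhang_yu_rr", "exact_odds"):
        raise ValueError(f"unknown adjustment mode {mode!r}")

    odds_ratio = np.asarray(odds_ratio, dtype=float)
    out = base.copy()
    tmask = [s in targets for s in CHRONIC_NAMES]
    for i in range(4):
        if tmask[i]:
            continue
        for j in range(4):
            if i == j or not tmask[j]:
                continue
            p = base[..., i, j]
            if mode == "zhang_yu_rr":
                p0 = (p if fixed_reference_risk is None
                      else np.asarray(fixed_reference_risk, dtype=float))
                rr = or_to_rr(odds_ratio, p0)
                newp = p / rr
            else:
                odds = p / (1.0 - p)
                odds = odds / odds_ratio
                newp = odds / (1.0 + odds)
            out[..., i, j] = newp
            out[..., i, i] += p - newp

    if strict:
        if np.any((out < -1e-12) | (out > 1 + 1e-12)):
            raise ValueError("adjustment produced a probability outside [0, 1]")
        out = np.clip(out, 0.0, 1.0)
    return out
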