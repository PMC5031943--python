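"""Numerically stable standard-normal tail arithmetic.

The conditional estimators reduce to ratios of phi/Phi differences over
unions of intervals whose standardized endpoints can sit eight or more SDs
into a tail (genome-wide-significant z-scores land exactly there).  Naive
evaluation underflows to 0/0.  Everything here works through the scaled
complementary error function erfcx, factoring out the dominant Gaussian
exponent so that ratios stay finite for |W| in the hundreds.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import erfcx, ndtr

_SQRT2 = math.sqrt(2.0)
_SQRT_2PI = math.sqrt(2.0 * math.pi)

from .exceptions import MassUnderflowError


def inverse_mills(w):
    """phi(w) / Phi(w), stable for arbitrarily negative w (vectorized).

    Uses the identity Phi(w) = erfcx(-w/sqrt2) * exp(-w^2/2) / 2, so the
    ratio is sqrt(2/pi)/erfcx(-w/sqrt2) with no explicit tail probability.
    erfcx overflows for large *positive* w, where the ratio is simply phi(w).
    """
    w = np.asarray(w, dtype=float)
    wc = np.minimum(w, 25.0)  # erfcx(-w/sqrt2) overflows near w ~ 38
    via_erfcx = math.sqrt(2.0 / math.pi) / erfcx(-wc / _SQRT2)
    deep_right = np.exp(-0.5 * np.square(w)) / _SQRT_2PI  # Phi(w) ~ 1 there
    out = np.where(w < 25.0, via_erfcx, deep_right)
    if out.ndim == 0:
        return float(out)
    return out


def _scaled_phi(w: float, c: float) -> float:
    """exp(c) * phi(w); exponent c - w^2/2 is guaranteed <= 0 by callers."""
    if math.isinf(w):
        return 0.0
    return math.exp(c - 0.5 * w * w) / _SQRT_2PI


def _scaled_tailmass(w_lo: float, w_hi: float, c: float) -> float:
    """exp(c) * (Phi(w_hi) - Phi(w_lo)) without underflow.

    Callers guarantee c <= min over the interval of w^2/2, so every exponent
    below is non-positive.
    """
    if w_lo >= 0.0:  # right tail: Phi(hi)-Phi(lo) = Phibar(lo)-Phibar(hi)
        lo_term = 0.5 * erfcx(w_lo / _SQRT2) * math.exp(c - 0.5 * w_lo * w_lo)
        hi_term = (
            0.0
            if math.isinf(w_hi)
            else 0.5 * erfcx(w_hi / _SQRT2) * math.exp(c - 0.5 * w_hi * w_hi)
        )
        return lo_term - hi_term
    if w_hi <= 0.0:  # left tail, by symmetry
        hi_term = 0.5 * erfcx(-w_hi / _SQRT2) * math.exp(c - 0.5 * w_hi * w_hi)
        lo_term = (
            0.0
            if math.isinf(w_lo)
            else 0.5 * erfcx(-w_lo / _SQRT2) * math.exp(c - 0.5 * w_lo * w_lo)
        )
        return hi_term - lo_term
    # straddles zero: mass is O(1) and c <= 0
    return math.exp(c) * (ndtr(w_hi) - ndtr(w_lo))


def truncated_standard_moments(w_intervals: Sequence[tuple[float, float]]):
    """Mean of a standard normal truncated to a union of [w_lo, w_hi].

    Returns ``(ratio, mass, log_mass)`` where the truncated mean is
    ``-ratio`` — i.e. ratio = sum(phi(w_hi)-phi(w_lo)) / sum(Phi diffs) — and
    ``mass`` is the total untruncated probability of the union (may underflow
    to 0.0 as a float; ``log_mass`` stays informative).

    Raises :class:`MassUnderflowError` if the scaled denominator is not a
    positive finite number.
    """
    if not w_intervals:
        raise ValueError("empty interval union")
    # dominant exponent: the smallest w^2/2 attained anywhere in the union
    exps = []
    for w_lo, w_hi in w_intervals:
        if w_lo <= 0.0 <= w_hi:
            exps.append(0.0)
        else:
            edge = min(abs(w_lo), abs(w_hi))
            exps.append(0.5 * edge * edge)
    c = min(exps)

    num = 0.0
    den = 0.0
    for w_lo, w_hi in w_intervals:
        num += _scaled_phi(w_hi, c) - _scaled_phi(w_lo, c)
        den += _scaled_tailmass(w_lo, w_hi, c)
    if not (den > 0.0) or not math.isfinite(den):
        ws = [(round(a, 4), round(b, 4)) for a, b in w_intervals]
        raise MassUnderflowError(
            f"conditional mass underflowed (scaled den={den!r}) for "
            f"standardized intervals {ws}"
        )
    log_mass = math.log(den) - c
    mass = math.exp(log_mass) if log_mass > -745.0 else 0.0
    return num / den, mass, log_mass
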