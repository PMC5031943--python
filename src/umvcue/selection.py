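"""Selection events and truncation sets.

A two-stage design conditions on the observed stage-1 outcome of selection:
the candidates' ranking (by effect size, one-sided z, or two-sided |z|) and,
for p-value rules, the significance threshold the last-ranked candidate
cleared.  Given the sufficient statistic for a target rank j, each ranking
constraint is *linear* in the unknown stage-2 value y, so the set of y
compatible with the observed data is an exact finite union of closed
intervals.  This module builds that set symbolically, by sign analysis of
each constraint's slope — no numeric root finding.

Sign conventions: with v the j-th covariance column and Z the sufficient
statistic, the stage-1 vector implied by a candidate stage-2 value y is
X_i(y) = Z_i - (v_i / tau_j^2) y, and every event constraint is an
inequality between linear functions of y.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .data import StudyData
from .exceptions import EventViolationError, InputError
from .intervals import IntervalSet, halfline_ge, halfline_ge_or_empty

logger = logging.getLogger(__name__)

ORDERINGS = ("effect", "p_one_sided", "p_two_sided")

#: Relative slack when verifying (not solving) ordering constraints on the
#: observed data: printed summary statistics are rounded, and exact ties must
#: not be rejected.
_EVENT_REL_TOL = 1e-9


@dataclass(frozen=True)
class SelectionRule:
    """How stage-1 candidates were ranked and thresholded.

    ``ordering``:
      * ``effect`` — ranked by raw effect X (no threshold);
      * ``p_one_sided`` — ranked by X/sigma, last rank above
        ``Phi^-1(1 - p_crit)``;
      * ``p_two_sided`` — ranked by |X|/sigma, last rank above
        ``Phi^-1(1 - p_crit/2)``.
    """

    ordering: str = "p_two_sided"
    p_crit: float = 1e-4

    def __post_init__(self) -> None:
        if self.ordering not in ORDERINGS:
            raise InputError(f"ordering must be one of {ORDERINGS}")
        if not 0.0 < self.p_crit <= 1.0:
            raise InputError("p_crit must be in (0, 1]")

    @property
    def threshold(self) -> float:
        """The z-scale cutoff c implied by p_crit (-inf when vacuous)."""
        if self.ordering == "effect":
            return -math.inf
        if self.ordering == "p_one_sided":
            return float(ndtri(1.0 - self.p_crit))
        return float(ndtri(1.0 - self.p_crit / 2.0))

    def keys(self, x: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """The ranking statistic for each candidate."""
        if self.ordering == "effect":
            return np.asarray(x, dtype=float)
        if self.ordering == "p_one_sided":
            return np.asarray(x, dtype=float) / np.asarray(sigma, dtype=float)
        return np.abs(x) / np.asarray(sigma, dtype=float)


@dataclass(frozen=True)
class TruncationSet:
    """Stage-2 values compatible with the observed sufficient statistic and
    the selection event: a disjoint union of closed intervals."""

    iset: IntervalSet

    def __post_init__(self) -> None:
        if self.iset.is_empty:
            raise InputError("truncation set cannot be empty")

    @property
    def intervals(self):
        return self.iset.intervals

    @property
    def M(self) -> int:
        return len(self.iset)

    def contains(self, y: float, tol: float = 0.0) -> bool:
        return self.iset.contains(y, tol)

    def standardized(self, m: float, s: float) -> list[tuple[float, float]]:
        """Endpoints (y - m)/s, ready for truncated-normal arithmetic."""
        return [((iv.lo - m) / s, (iv.hi - m) / s) for iv in self.iset.intervals]

    def to_json(self) -> str:
        return self.iset.to_json()


# ---------------------------------------------------------------------------
# event verification
# ---------------------------------------------------------------------------

def check_event(study: StudyData, rule: SelectionRule) -> StudyData:
    """Verify the observed stage-1 estimates satisfy the selection event.

    Candidates must already be listed in rank order; a violated inequality is
    an error naming the offending pair, because silently re-sorting would
    change the estimand the theory conditions on.  Exact ties (rounded
    inputs) are tolerated and logged.
    """
    keys = rule.keys(study.x, study.sigma)
    scale = max(1.0, float(np.max(np.abs(keys))))
    tol = _EVENT_REL_TOL * scale
    for i in range(study.K - 1):
        if keys[i] < keys[i + 1] - tol:
            raise EventViolationError(
                f"ranking violated between {study.snp_ids[i]} (rank {i + 1}, "
                f"key {keys[i]:.4f}) and {study.snp_ids[i + 1]} (rank {i + 2}, "
                f"key {keys[i + 1]:.4f}) under ordering {rule.ordering!r}"
            )
        if abs(keys[i] - keys[i + 1]) <= tol:
            logger.warning(
                "exact ranking tie between %s and %s (key %.4f): inputs are "
                "likely rounded; keeping input order",
                study.snp_ids[i], study.snp_ids[i + 1], keys[i],
            )
    c = rule.threshold
    if math.isfinite(c) and keys[-1] < c - tol:
        raise EventViolationError(
            f"last-ranked candidate {study.snp_ids[-1]} has key "
            f"{keys[-1]:.4f} below the threshold {c:.4f} "
            f"(p_crit={rule.p_crit:g}); the selection event does not hold"
        )
    return study


# ---------------------------------------------------------------------------
# the linear geometry of the event in y
# ---------------------------------------------------------------------------

def implied_stage1(
    y: float, z: np.ndarray, vcol: np.ndarray, tau_j: float
) -> np.ndarray:
    """Stage-1 vector implied by stage-2 value y at fixed sufficient statistic:
    X_i(y) = Z_i - (v_i / tau_j^2) * y."""
    z = np.asarray(z, dtype=float)
    vcol = np.asarray(vcol, dtype=float)
    if z.shape != vcol.shape:
        raise InputError("z and vcol must have the same length")
    return z - vcol / tau_j**2 * y


def event_predicate(
    y: float,
    z: np.ndarray,
    vcol: np.ndarray,
    sigmas: np.ndarray,
    tau_j: float,
    rule: SelectionRule,
) -> bool:
    """Ground-truth membership test: does the stage-1 vector implied by y
    satisfy the selection event?  Used as the oracle the interval algebra is
    validated against; deliberately knows nothing about interval sets."""
    xs = implied_stage1(y, z, vcol, tau_j)
    keys = rule.keys(xs, np.asarray(sigmas, dtype=float))
    if np.any(keys[:-1] < keys[1:]):
        return False
    c = rule.threshold
    return not (math.isfinite(c) and keys[-1] < c)


# ---------------------------------------------------------------------------
# truncation-set builders
# ---------------------------------------------------------------------------

def _coef_scale(vcol: np.ndarray, sigmas: np.ndarray, tau_j: float) -> float:
    """Characteristic magnitude of the y-slopes, for the zero-slope test."""
    return float(np.max(np.abs(vcol)) / tau_j**2 / max(np.min(sigmas), 1e-30))


def truncation_effect(
    z: np.ndarray, vcol: np.ndarray, tau_j: float
) -> TruncationSet:
    """Effect-size ordering: X_1(y) >= ... >= X_K(y).

    Each neighbour constraint (Z_i - Z_{i+1}) - ((v_i - v_{i+1})/tau^2) y >= 0
    is a half-line; the intersection is a single interval
    [max over positive-gap pairs, min over negative-gap pairs].
    """
    z = np.asarray(z, dtype=float)
    vcol = np.asarray(vcol, dtype=float)
    t2 = tau_j**2
    scale = float(np.max(np.abs(vcol))) / t2 if len(vcol) else 1.0
    out = IntervalSet.full()
    for i in range(len(z) - 1):
        out = out.intersect(
            halfline_ge(z[i] - z[i + 1], -(vcol[i] - vcol[i + 1]) / t2, scale)
        )
    if out.is_empty:
        raise_inconsistent()
    return TruncationSet(out)


def truncation_p_one(
    z: np.ndarray,
    vcol: np.ndarray,
    sigmas: np.ndarray,
    tau_j: float,
    c: float,
) -> TruncationSet:
    """One-sided p-value ordering: X_1(y)/s_1 >= ... >= X_K(y)/s_K >= c."""
    z = np.asarray(z, dtype=float)
    vcol = np.asarray(vcol, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    t2 = tau_j**2
    K = len(z)
    scale = _coef_scale(vcol, sigmas, tau_j)
    out = IntervalSet.full()
    for i in range(K - 1):
        out = out.intersect(
            halfline_ge(
                z[i] / sigmas[i] - z[i + 1] / sigmas[i + 1],
                -(vcol[i] / sigmas[i] - vcol[i + 1] / sigmas[i + 1]) / t2,
                scale,
            )
        )
    if math.isfinite(c):
        out = out.intersect(
            halfline_ge(z[K - 1] / sigmas[K - 1] - c, -vcol[K - 1] / (sigmas[K - 1] * t2), scale)
        )
    if out.is_empty:
        raise_inconsistent()
    return TruncationSet(out)


def truncation_p_two(
    z: np.ndarray,
    vcol: np.ndarray,
    sigmas: np.ndarray,
    tau_j: float,
    c: float,
) -> TruncationSet:
    """Two-sided p-value ordering: |X_1(y)|/s_1 >= ... >= |X_K(y)|/s_K >= c.

    Each neighbour constraint |X_i|/s_i >= |X_{i+1}|/s_{i+1} factors into
    (difference >= 0 and sum >= 0) or (difference <= 0 and sum <= 0), where
    difference = X_i/s_i - X_{i+1}/s_{i+1} and sum = X_i/s_i + X_{i+1}/s_{i+1}
    are both linear in y.  The threshold on the last rank is the union of two
    tails.  The result is a disjoint union of up to 2K closed intervals.
    """
    z = np.asarray(z, dtype=float)
    vcol = np.asarray(vcol, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    t2 = tau_j**2
    K = len(z)
    scale = _coef_scale(vcol, sigmas, tau_j)
    out = IntervalSet.full()
    for i in range(K - 1):
        d0 = z[i] / sigmas[i] - z[i + 1] / sigmas[i + 1]
        d1 = -(vcol[i] / sigmas[i] - vcol[i + 1] / sigmas[i + 1]) / t2
        s0 = z[i] / sigmas[i] + z[i + 1] / sigmas[i + 1]
        s1 = -(vcol[i] / sigmas[i] + vcol[i + 1] / sigmas[i + 1]) / t2
        both_pos = halfline_ge_or_empty(d0, d1, scale).intersect(
            halfline_ge_or_empty(s0, s1, scale)
        )
        both_neg = halfline_ge_or_empty(-d0, -d1, scale).intersect(
            halfline_ge_or_empty(-s0, -s1, scale)
        )
        out = out.intersect(both_pos.union(both_neg))
    if math.isfinite(c) and c > 0:
        t0 = z[K - 1] / sigmas[K - 1]
        t1 = -vcol[K - 1] / (sigmas[K - 1] * t2)
        upper = halfline_ge_or_empty(t0 - c, t1, scale)
        lower = halfline_ge_or_empty(-t0 - c, -t1, scale)
        out = out.intersect(upper.union(lower))
    if out.is_empty:
        raise_inconsistent()
    return TruncationSet(out)


def truncation_for_rule(
    z: np.ndarray,
    vcol: np.ndarray,
    sigmas: np.ndarray,
    tau_j: float,
    rule: SelectionRule,
) -> TruncationSet:
    """Dispatch to the rule's truncation builder."""
    if rule.ordering == "effect":
        return truncation_effect(z, vcol, tau_j)
    if rule.ordering == "p_one_sided":
        return truncation_p_one(z, vcol, sigmas, tau_j, rule.threshold)
    return truncation_p_two(z, vcol, sigmas, tau_j, rule.threshold)


def raise_inconsistent() -> None:
    from .exceptions import InconsistentTruncationError

    raise InconsistentTruncationError(
        "truncation set is empty: the observed data do not satisfy the "
        "selection event (was check_event bypassed?)"
    )
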