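"""Closed-interval sets on the real line.

The truncation sets that drive the conditional estimators are finite unions
of closed intervals (possibly unbounded on either side).  This module gives
them an exact, canonical representation with intersection/union, built from
linear half-line constraints solved symbolically by the sign of the slope —
never by numeric root finding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import InconsistentTruncationError

#: Absolute tolerance (on the coefficient scale) below which the slope of a
#: linear constraint is declared zero, i.e. the constraint is y-free.  Exact
#: cancellation arises only at degeneracies such as sigma1/sigma2 == rho.
COEF_ZERO_TOL = 1e-12

#: Relative seam tolerance for merging adjacent intervals produced by
#: intersecting many half-lines in floating point.
MERGE_REL_TOL = 1e-14


@dataclass(frozen=True)
class Interval:
    """A closed interval [lo, hi]; lo may be -inf, hi may be +inf."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if math.isnan(self.lo) or math.isnan(self.hi):
            raise ValueError("interval endpoint is NaN")
        if self.lo > self.hi:
            raise ValueError(f"empty interval [{self.lo}, {self.hi}]")

    def contains(self, y: float, tol: float = 0.0) -> bool:
        return self.lo - tol <= y <= self.hi + tol


class IntervalSet:
    """A canonical (sorted, disjoint) finite union of closed intervals."""

    __slots__ = ("intervals",)

    def __init__(self, intervals: Iterable[Interval] = (), _canonical: bool = False):
        ivs = tuple(intervals)
        if not _canonical:
            ivs = _canonicalize(ivs)
        self.intervals: tuple[Interval, ...] = ivs

    # -- constructors ------------------------------------------------------
    @staticmethod
    def full() -> "IntervalSet":
        return IntervalSet((Interval(-math.inf, math.inf),), _canonical=True)

    @staticmethod
    def empty() -> "IntervalSet":
        return IntervalSet((), _canonical=True)

    @staticmethod
    def closed(lo: float, hi: float) -> "IntervalSet":
        return IntervalSet((Interval(lo, hi),), _canonical=True)

    # -- predicates --------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return not self.intervals

    @property
    def is_full(self) -> bool:
        return (
            len(self.intervals) == 1
            and self.intervals[0].lo == -math.inf
            and self.intervals[0].hi == math.inf
        )

    def contains(self, y: float, tol: float = 0.0) -> bool:
        return any(iv.contains(y, tol) for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __hash__(self) -> int:
        return hash(self.intervals)

    def __repr__(self) -> str:
        body = " U ".join(f"[{iv.lo:.6g}, {iv.hi:.6g}]" for iv in self.intervals)
        return f"IntervalSet({body or 'empty'})"

    # -- algebra -----------------------------------------------------------
    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: list[Interval] = []
        for a in self.intervals:
            for b in other.intervals:
                lo, hi = max(a.lo, b.lo), min(a.hi, b.hi)
                if lo <= hi:
                    out.append(Interval(lo, hi))
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self.intervals + other.intervals)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps([[iv.lo, iv.hi] for iv in self.intervals])


def _canonicalize(intervals: Sequence[Interval]) -> tuple[Interval, ...]:
    """Sort and merge intervals that overlap within a floating-point seam."""
    if not intervals:
        return ()
    ivs = sorted(intervals, key=lambda iv: (iv.lo, iv.hi))
    scale = max(
        (abs(e) for iv in ivs for e in (iv.lo, iv.hi) if math.isfinite(e)),
        default=1.0,
    )
    gap = MERGE_REL_TOL * max(scale, 1.0)
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.lo <= last.hi + gap:
            if iv.hi > last.hi:
                out[-1] = Interval(last.lo, iv.hi)
        else:
            out.append(iv)
    return tuple(out)


def halfline_ge(c0: float, c1: float, scale: float = 1.0) -> IntervalSet:
    """Solve the linear constraint ``c0 + c1*y >= 0`` for y.

    The slope ``c1`` is classified as positive, negative or zero at absolute
    tolerance ``COEF_ZERO_TOL * max(scale, 1)``.  A zero-slope (y-free)
    constraint must already hold on the observed data; if it does not, the
    selection event was never verified and we fail loudly.
    """
    tol = COEF_ZERO_TOL * max(abs(scale), 1.0)
    if abs(c1) <= tol:
        if c0 >= -tol:
            return IntervalSet.full()
        raise InconsistentTruncationError(
            f"y-free constraint {c0:.6g} >= 0 is violated; "
            "the selection event does not hold for these data "
            "(was check_event bypassed?)"
        )
    if c1 > 0:
        return IntervalSet.closed(-c0 / c1, math.inf)
    return IntervalSet.closed(-math.inf, -c0 / c1)


def halfline_ge_or_empty(c0: float, c1: float, scale: float = 1.0) -> IntervalSet:
    """Like :func:`halfline_ge` but a violated y-free constraint yields the
    empty set instead of raising.  Used inside unions, where one branch of a
    disjunction may legitimately be infeasible."""
    tol = COEF_ZERO_TOL * max(abs(scale), 1.0)
    if abs(c1) <= tol:
        return IntervalSet.full() if c0 >= -tol else IntervalSet.empty()
    if c1 > 0:
        return IntervalSet.closed(-c0 / c1, math.inf)
    return IntervalSet.closed(-math.inf, -c0 / c1)
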