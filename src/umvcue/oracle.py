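"""Independent brute-force ground truth for the conditional estimators.

Two oracles, both deliberately ignorant of the interval algebra:

* :func:`oracle_conditional_mean` integrates y * phi((y-m)/s) restricted to
  the raw event predicate by adaptive quadrature, splitting at predicate
  sign changes located by bisection.  The predicate is piecewise constant in
  y with at most ~2K breakpoints, so this is exact to quadrature tolerance.
* :func:`oracle_mc_two_stage` simulates the full two-stage process
  (correlated stage-1 draws, ranking/thresholding, stage-2 draws) by
  rejection, for selection-conditioned sampling checks.

This is a validation facility, not a performance path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import norm

from .data import StudyData
from .exceptions import MassUnderflowError, UmvcueError
from .estimators import ConditionalLaw, sufficient_stats
from .selection import SelectionRule, check_event, event_predicate


@dataclass(frozen=True)
class OracleSpec:
    """Quadrature / Monte-Carlo controls for the oracles."""

    grid_halfwidth: float = 12.0  # conditional SDs to integrate over
    rel_tol: float = 1e-9
    mc_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_halfwidth < 8:
            raise ValueError("grid_halfwidth must be >= 8 conditional SDs")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


_BISECT_TOL = 1e-13
_SCAN_POINTS = 4001


def _predicate_pieces(pred, lo: float, hi: float) -> list[tuple[float, float]]:
    """Maximal sub-intervals of [lo, hi] on which ``pred`` is true, located
    by a fine scan plus bisection of each sign change."""
    ts = np.linspace(lo, hi, _SCAN_POINTS)
    vals = np.array([pred(t) for t in ts], dtype=bool)
    edges: list[float] = []
    for i in range(len(ts) - 1):
        if vals[i] != vals[i + 1]:
            a, b = ts[i], ts[i + 1]
            fa = vals[i]
            while b - a > _BISECT_TOL * max(1.0, abs(a), abs(b)):
                mid = 0.5 * (a + b)
                if pred(mid) == fa:
                    a = mid
                else:
                    b = mid
            edges.append(0.5 * (a + b))
    bounds = [lo, *edges, hi]
    pieces = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a and pred(0.5 * (a + b)):
            pieces.append((a, b))
    return pieces


def oracle_conditional_mean(
    study: StudyData,
    rule: SelectionRule,
    j: int,
    spec: OracleSpec = OracleSpec(),
) -> float:
    """E(Y_j | Z, selection event) by adaptive quadrature over the raw event
    predicate, in standardized coordinates t = (y - m)/s."""
    check_event(study, rule)
    jj = j - 1
    z = sufficient_stats(study, j)
    vcol = study.V[:, jj]
    tau_j = float(study.tau[jj])
    law = ConditionalLaw.from_stats(float(z[jj]), float(study.sigma[jj]), tau_j)

    def pred(t: float) -> bool:
        return event_predicate(law.m + law.s * t, z, vcol, study.sigma, tau_j, rule)

    H = spec.grid_halfwidth
    pieces = _predicate_pieces(pred, -H, H)
    if not pieces:
        raise MassUnderflowError(
            "event predicate is false everywhere within the integration "
            f"window of +/-{H} conditional SDs"
        )
    num = 0.0
    den = 0.0
    with warnings.catch_warnings():
        # pieces deep in a tail trip quad's roundoff heuristic; accuracy is
        # governed by the den > 0 check and the equivalence tests
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        for a, b in pieces:
            num += integrate.quad(lambda t: t * norm.pdf(t), a, b,
                                  epsrel=spec.rel_tol, epsabs=1e-15, limit=200)[0]
            den += integrate.quad(norm.pdf, a, b,
                                  epsrel=spec.rel_tol, epsabs=1e-15, limit=200)[0]
    if not (den > 0.0) or not math.isfinite(den):
        raise MassUnderflowError(
            f"quadrature mass underflowed (den={den!r}) over pieces {pieces}"
        )
    return law.m + law.s * num / den


def oracle_mc_two_stage(
    mu: np.ndarray,
    V: np.ndarray,
    taus: np.ndarray,
    rule: SelectionRule,
    n: int,
    seed: int,
) -> dict:
    """Simulate the two-stage process n times.

    Per replicate: draw X ~ N(mu, V); rank by the rule's statistic; accept
    the replicate iff every candidate clears the rule's threshold (the
    selection event with all K candidates retained); draw stage-2 estimates
    Y_rank ~ N(mu_(rank), tau_rank^2) in rank order.

    Returns arrays ``x`` (n_acc x K, original candidate order), ``perm``
    (n_acc x K, perm[r, i] = candidate index at rank i+1), ``y`` (n_acc x K,
    rank order), plus ``n_proposed``/``accept_rate``.  Reproducible under
    ``seed``.
    """
    mu = np.asarray(mu, dtype=float)
    V = np.asarray(V, dtype=float)
    taus = np.broadcast_to(np.asarray(taus, dtype=float), mu.shape)
    np.linalg.cholesky(V)  # PD check
    rng = np.random.default_rng(seed)
    K = len(mu)
    c = rule.threshold

    xs: list[np.ndarray] = []
    n_proposed = 0
    batch = max(n, 1000)
    max_proposals = 1000 * n + batch
    while sum(len(a) for a in xs) < n:
        if n_proposed >= max_proposals:
            raise UmvcueError(
                f"zero or too few acceptances after {n_proposed} proposals "
                f"under p_crit={rule.p_crit:g}; increase n or relax p_crit"
            )
        draw = rng.multivariate_normal(mu, V, size=batch, method="cholesky")
        n_proposed += batch
        if math.isfinite(c):
            keys = rule.keys(draw.T, np.sqrt(np.diag(V))[:, None]).T
            draw = draw[np.min(keys, axis=1) >= c]
        xs.append(draw)
    x = np.concatenate(xs)[:n]
    keys = rule.keys(x.T, np.sqrt(np.diag(V))[:, None]).T
    # descending rank; stable so ties keep candidate order
    perm = np.argsort(-keys, axis=1, kind="stable")
    mu_ranked = mu[perm]
    y = rng.standard_normal((n, K)) * taus[None, :] + mu_ranked
    return {
        "x": x,
        "perm": perm,
        "y": y,
        "n_proposed": n_proposed,
        "accept_rate": n / n_proposed,
    }
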