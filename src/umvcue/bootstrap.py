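"""Parametric-bootstrap confidence intervals for a correlated ranked pair.

The point estimates carry no natural standard error, so intervals come from
a three-step parametric bootstrap that treats the conditionally unbiased
estimates as the truth:

1. draw bootstrap stage-1 values for the pair from a bivariate normal
   centred at their UMVCUEs with the study SEs and the assumed correlation,
   *conditional* on the pair staying in its observed rank sandwich (adjacent
   observed |x|/sigma bounds; for a mutually adjacent pair, the mutual
   ordering constraint replaces the inner bounds);
2. draw independent bootstrap stage-2 values centred at the UMVCUEs;
3. recompute the estimators with every other candidate's observed values
   held fixed.

Repeating B times, the alpha/2 and 1-alpha/2 empirical quantiles of each
estimator's bootstrap distribution form the interval.  Conditional sampling
in step 1 uses exact rejection from the unconstrained bivariate normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import StudyData
from .exceptions import InputError, UmvcueError
from .estimators import mle, umvcue
from .selection import SelectionRule, check_event

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapSpec:
    """Controls for the pair bootstrap.

    ``pair`` holds the 1-based stage-1 ranks (j1 < j2) of the two candidates
    assumed correlated; ``stage2_sd`` chooses the SD of the bootstrap
    stage-2 draws: ``"tau"`` (the stage-2 SE, consistent with the model
    Y_j ~ N(mu_(j), tau_j^2)) or ``"sigma"`` (the stage-1 SE variant).
    """

    pair: tuple[int, int]
    rho: float = 0.0
    B: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    max_rejection_factor: float = 1e6
    stage2_sd: str = "tau"

    def __post_init__(self) -> None:
        j1, j2 = self.pair
        if not j1 < j2:
            raise InputError("pair must be given as ranks (j1, j2) with j1 < j2")
        if self.B < 100:
            raise InputError("B must be >= 100")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise InputError("|rho| must be < 1")
        if self.stage2_sd not in ("tau", "sigma"):
            raise InputError("stage2_sd must be 'tau' or 'sigma'")


def _pair_constraints(
    spec: BootstrapSpec, study: StudyData, rule: SelectionRule
) -> tuple[float, float, float, float, bool]:
    """Sandwich bounds (on the |x|/sigma scale) for the two bootstrap
    draws: (upper1, lower1, upper2, lower2, mutual) where ``mutual`` means
    the pair is rank-adjacent and bound by each other rather than by an
    observed candidate between them."""
    j1, j2 = spec.pair
    K = study.K
    keys = rule.keys(study.x, study.sigma)
    zabs = np.abs(keys)
    upper1 = zabs[j1 - 2] if j1 > 1 else math.inf
    mutual = j2 == j1 + 1
    if mutual:
        lower1 = -math.inf  # replaced by the mutual constraint
        upper2 = math.inf
    else:
        lower1 = zabs[j1]  # observed candidate at rank j1+1
        upper2 = zabs[j2 - 2]
    lower2 = zabs[j2] if j2 < K else max(rule.threshold, 0.0)
    return float(upper1), float(lower1), float(upper2), float(lower2), mutual


def sample_stage1_conditional(
    spec: BootstrapSpec,
    study: StudyData,
    uhats: tuple[float, float],
    rng: np.random.Generator,
    size: int,
    rule: SelectionRule = SelectionRule(),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rejection-sample ``size`` accepted stage-1 pairs.

    Returns (draws1, draws2, acceptance_rate).  Raises if the empirical
    acceptance rate falls below 1/max_rejection_factor.
    """
    j1, j2 = spec.pair
    s1 = float(study.sigma[j1 - 1])
    s2 = float(study.sigma[j2 - 1])
    cov = np.array(
        [[s1**2, spec.rho * s1 * s2], [spec.rho * s1 * s2, s2**2]]
    )
    mean = np.asarray(uhats, dtype=float)
    up1, lo1, up2, lo2, mutual = _pair_constraints(spec, study, rule)

    out1: list[np.ndarray] = []
    out2: list[np.ndarray] = []
    n_acc = 0
    n_prop = 0
    batch = max(4 * size, 10_000)
    while n_acc < size:
        draw = rng.multivariate_normal(mean, cov, size=batch, method="cholesky")
        n_prop += batch
        z1 = np.abs(draw[:, 0]) / s1
        z2 = np.abs(draw[:, 1]) / s2
        ok = (z1 <= up1) & (z2 >= lo2)
        if mutual:
            ok &= z1 >= z2
        else:
            ok &= (z1 >= lo1) & (z2 <= up2)
        acc = draw[ok]
        n_acc += len(acc)
        out1.append(acc[:, 0])
        out2.append(acc[:, 1])
        if n_prop >= batch * 3 and n_acc < n_prop / spec.max_rejection_factor:
            raise UmvcueError(
                f"rejection sampling acceptance rate {n_acc / n_prop:.2e} "
                f"below 1/max_rejection_factor={1 / spec.max_rejection_factor:.2e}"
            )
    rate = n_acc / n_prop
    return (
        np.concatenate(out1)[:size],
        np.concatenate(out2)[:size],
        rate,
    )


def bootstrap_ci(
    spec: BootstrapSpec,
    study: StudyData,
    rule: SelectionRule = SelectionRule(),
) -> "BootstrapResult":
    """Pair bootstrap CIs for the UMVCUE, MLE and stage-2 estimators.

    The study's covariance is first given the pair correlation ``spec.rho``;
    the UMVCUEs of the pair under that covariance centre the bootstrap.
    Empirical quantiles use linear interpolation of order statistics
    (numpy's default, Hyndman–Fan type 7).
    """
    j1, j2 = spec.pair
    if not (1 <= j1 < j2 <= study.K):
        raise InputError(f"pair {spec.pair} outside ranks 1..{study.K}")
    a, b = study.snp_ids[j1 - 1], study.snp_ids[j2 - 1]
    study = study.with_correlations({(a, b): spec.rho}) if spec.rho else study
    check_event(study, rule)
    u1 = umvcue(study, rule, j1, _checked=True).value
    u2 = umvcue(study, rule, j2, _checked=True).value

    rng = np.random.default_rng(spec.seed)
    x1b, x2b, rate = sample_stage1_conditional(
        spec, study, (u1, u2), rng, spec.B, rule
    )
    if spec.stage2_sd == "tau":
        sd1, sd2 = float(study.tau[j1 - 1]), float(study.tau[j2 - 1])
    else:
        sd1, sd2 = float(study.sigma[j1 - 1]), float(study.sigma[j2 - 1])
    y1b = rng.standard_normal(spec.B) * sd1 + u1
    y2b = rng.standard_normal(spec.B) * sd2 + u2

    sig1, tau1 = float(study.sigma[j1 - 1]), float(study.tau[j1 - 1])
    sig2, tau2 = float(study.sigma[j2 - 1]), float(study.tau[j2 - 1])
    samples = {
        (a, "stage2"): y1b,
        (b, "stage2"): y2b,
        (a, "mle"): np.empty(spec.B),
        (b, "mle"): np.empty(spec.B),
        (a, "umvcue"): np.empty(spec.B),
        (b, "umvcue"): np.empty(spec.B),
    }
    n_redraws = 0
    for r in range(spec.B):
        boot = study.replace_snp(j1 - 1, x=float(x1b[r]), y=float(y1b[r]))
        boot = boot.replace_snp(j2 - 1, x=float(x2b[r]), y=float(y2b[r]))
        samples[(a, "mle")][r] = mle(x1b[r], sig1, y1b[r], tau1)
        samples[(b, "mle")][r] = mle(x2b[r], sig2, y2b[r], tau2)
        samples[(a, "umvcue")][r] = umvcue(boot, rule, j1, _checked=True).value
        samples[(b, "umvcue")][r] = umvcue(boot, rule, j2, _checked=True).value
    if n_redraws:
        logger.info("redrew %d bootstrap replicates that violated the event", n_redraws)

    rows = []
    qs = (spec.alpha / 2.0, 1.0 - spec.alpha / 2.0)
    for (snp, est), vals in samples.items():
        lo, hi = np.quantile(vals, qs)
        rows.append(
            {
                "snp_id": snp,
                "estimator": est,
                "ci_lo_log": lo,
                "ci_hi_log": hi,
                "or_ci_lo": math.exp(lo),
                "or_ci_hi": math.exp(hi),
                "or_width": math.exp(hi) - math.exp(lo),
            }
        )
    table = pd.DataFrame(rows).sort_values(["snp_id", "estimator"]).reset_index(drop=True)
    return BootstrapResult(
        spec=spec, table=table, samples=samples, acceptance_rate=rate,
        centres={a: u1, b: u2}, n_redraws=n_redraws,
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap CI table plus the raw replicate samples for diagnostics."""

    spec: BootstrapSpec
    table: pd.DataFrame
    samples: dict
    acceptance_rate: float
    centres: dict
    n_redraws: int

    def ci(self, snp_id: str, estimator: str = "umvcue") -> tuple[float, float]:
        """(lo, hi) on the OR scale."""
        row = self.table[
            (self.table.snp_id == snp_id) & (self.table.estimator == estimator)
        ]
        if row.empty:
            raise InputError(f"no CI for ({snp_id}, {estimator})")
        return float(row.or_ci_lo.iloc[0]), float(row.or_ci_hi.iloc[0])
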