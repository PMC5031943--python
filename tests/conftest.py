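"""Shared fixtures: the bundled study, and a generator of random valid
post-selection instances (data that genuinely satisfy their selection event,
obtained by ranking simulated stage-1 draws)."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from scipy.stats import norm, random_correlation

from umvcue import SelectionRule, SnpSummary, StudyData, parkes_table1

logging.getLogger("umvcue").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def parkes() -> StudyData:
    return parkes_table1()


@pytest.fixture(scope="session")
def parkes_rule() -> SelectionRule:
    # weakest threshold consistent with the printed rank-11 z of 4.06;
    # y-free for every estimate here, so its exact value is immaterial
    return SelectionRule("p_two_sided", 1e-4)


def random_instance(
    rng: np.random.Generator,
    K: int,
    ordering: str,
    max_abs_rho: float = 0.95,
    threshold_slack: float = 0.3,
):
    """One random post-selection dataset satisfying its own event.

    Draws a random correlation structure (|rho| <= max_abs_rho), simulates
    stage-1 estimates, ranks them by the rule's statistic, and sets p_crit
    just below the realized minimum key so the threshold constraint is
    active but satisfied.  Returns (study, rule, j) with a random target
    rank j.
    """
    sig = rng.uniform(0.3, 1.5, K)
    if K > 1:
        ev = rng.uniform(0.2, 1.0, K)
        ev = ev / ev.sum() * K
        R = random_correlation.rvs(ev, random_state=rng)
        np.fill_diagonal(R, 1.0)
        R = np.clip(R, -max_abs_rho, max_abs_rho)
        np.fill_diagonal(R, 1.0)
        w = np.linalg.eigvalsh(R).min()
        if w < 1e-6:
            R = (R + np.eye(K) * (1e-5 - w)) / (1.0 + 1e-5 - w)
        V = R * np.outer(sig, sig)
    else:
        V = np.diag(sig**2)
    mu = rng.normal(0.0, 1.0, K)
    x = rng.multivariate_normal(mu, V)

    if ordering == "effect":
        keys = x
    elif ordering == "p_one_sided":
        keys = x / sig
    else:
        keys = np.abs(x) / sig
    order = np.argsort(-keys)
    x, sig, mu = x[order], sig[order], mu[order]
    V = V[np.ix_(order, order)]
    kmin = keys[order][-1]

    if ordering == "effect":
        p_crit = 1.0
    elif ordering == "p_one_sided":
        p_crit = float(np.clip(norm.sf(kmin - threshold_slack), 1e-12, 1.0))
    else:
        p_crit = float(np.clip(2.0 * norm.sf(max(kmin - threshold_slack, 0.0)), 1e-12, 1.0))
    rule = SelectionRule(ordering, p_crit)

    tau = rng.uniform(0.3, 1.5, K)
    y = rng.normal(mu, tau)
    snps = tuple(
        SnpSummary(f"s{i}", float(x[i]), float(sig[i]), float(y[i]), float(tau[i]))
        for i in range(K)
    )
    return StudyData(snps, V), rule, int(rng.integers(1, K + 1))
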