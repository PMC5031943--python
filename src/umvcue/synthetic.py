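"""Synthetic two-stage GWAS-style datasets with known truth.

Emulates the pipeline the estimators are built for: a large panel of
candidate variants with block-correlated stage-1 effect estimates, a
rank-and-threshold selection rule, and independent normal stage-2 estimates
for the survivors.  The survivors' covariance handed to the estimators is
the exact sub-matrix of the generating covariance (the known-covariance
assumption); optional noise on that matrix supports robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SnpSummary, StudyData
from .exceptions import InputError
from .selection import SelectionRule


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-condition description for one synthetic dataset.

    ``mu`` may be a scalar (shared true log-OR), a length-K_total vector, or
    a mixture spec ``(pi_nonnull, effect)`` drawing each candidate null with
    probability 1-pi and at ``effect`` otherwise.  ``blocks`` lists
    ``(size, rho)`` LD blocks tiling the panel in order; remaining
    candidates are independent.
    """

    K_total: int
    mu: object = 0.0
    blocks: tuple[tuple[int, float], ...] = ()
    sigmas: object = 0.05
    taus: object = 0.05
    rule: SelectionRule = field(default_factory=SelectionRule)
    seed: int = 0
    v_noise_sd: float = 0.0  # optional perturbation of the reported V

    def __post_init__(self) -> None:
        if self.K_total < 1:
            raise InputError("K_total must be >= 1")
        used = sum(size for size, _ in self.blocks)
        if used > self.K_total:
            raise InputError("blocks cover more candidates than K_total")
        for size, rho in self.blocks:
            if not -1.0 < rho < 1.0:
                raise InputError("block correlations must be strictly inside (-1, 1)")


def _resolve_mu(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    mu = spec.mu
    if isinstance(mu, tuple) and len(mu) == 2 and np.isscalar(mu[0]):
        pi, effect = mu
        return np.where(rng.random(spec.K_total) < pi, float(effect), 0.0)
    arr = np.broadcast_to(np.asarray(mu, dtype=float), (spec.K_total,))
    return arr.copy()


def build_covariance(spec: GeneratorSpec) -> np.ndarray:
    """Block-diagonal covariance from the blocks and sigmas."""
    sig = np.broadcast_to(np.asarray(spec.sigmas, dtype=float), (spec.K_total,))
    corr = np.eye(spec.K_total)
    start = 0
    for size, rho in spec.blocks:
        corr[start:start + size, start:start + size] = (
            rho * np.ones((size, size)) + (1 - rho) * np.eye(size)
        )
        start += size
    V = corr * np.outer(sig, sig)
    try:
        np.linalg.cholesky(V)
    except np.linalg.LinAlgError as e:
        raise InputError(
            "block covariance is not positive definite (an equicorrelated "
            "block of size m requires rho > -1/(m-1))"
        ) from e
    return V


def generate(spec: GeneratorSpec):
    """Draw one synthetic dataset.

    Returns ``(study, truth, log)``: the post-selection :class:`StudyData`
    (or None when nothing survives), a truth table for *all* candidates, and
    a selection log.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mu = _resolve_mu(spec, rng)
    V_full = build_covariance(spec)
    sig = np.sqrt(np.diag(V_full))
    tau = np.broadcast_to(np.asarray(spec.taus, dtype=float), (spec.K_total,))

    x = rng.multivariate_normal(mu, V_full, method="cholesky")
    keys = spec.rule.keys(x, sig)
    c = spec.rule.threshold
    survivors = np.flatnonzero(keys >= c) if np.isfinite(c) else np.arange(spec.K_total)
    # rank survivors by decreasing key; stable tie-break keeps panel order
    order = survivors[np.argsort(-keys[survivors], kind="stable")]

    truth = pd.DataFrame(
        {
            "candidate": np.arange(spec.K_total),
            "mu": mu,
            "sigma": sig,
            "x": x,
            "key": keys,
            "selected": np.isin(np.arange(spec.K_total), survivors),
        }
    )
    rank = np.full(spec.K_total, -1)
    rank[order] = np.arange(1, len(order) + 1)
    truth["rank"] = rank

    log = {
        "seed": spec.seed,
        "n_selected": int(len(order)),
        "threshold": float(c),
        "ordering": spec.rule.ordering,
    }
    if len(order) == 0:
        return None, truth, log

    y = rng.standard_normal(len(order)) * tau[order] + mu[order]
    snps = tuple(
        SnpSummary(
            snp_id=f"snp{idx:05d}",
            x=float(x[idx]),
            sigma=float(sig[idx]),
            y=float(y[i]),
            tau=float(tau[idx]),
        )
        for i, idx in enumerate(order)
    )
    V_sub = V_full[np.ix_(order, order)]
    if spec.v_noise_sd > 0:
        noise = rng.standard_normal(V_sub.shape) * spec.v_noise_sd
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        V_sub = V_sub + noise * np.outer(np.sqrt(np.diag(V_sub)), np.sqrt(np.diag(V_sub)))
    study = StudyData(snps, V_sub)
    return study, truth, log


def write_fixture(spec: GeneratorSpec, prefix) -> dict:
    """Write the generated dataset as the package's TSV dialects plus a
    truth table; returns the selection log."""
    from pathlib import Path

    study, truth, log = generate(spec)
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(f"{prefix}_truth.tsv", sep="\t", index=False)
    if study is not None:
        pd.DataFrame(
            {
                "snp_id": study.snp_ids,
                "x": study.x,
                "sigma": study.sigma,
                "y": study.y,
                "tau": study.tau,
            }
        ).to_csv(f"{prefix}_summary.tsv", sep="\t", index=False)
        corr = study.V / np.outer(study.sigma, study.sigma)
        pd.DataFrame(corr, index=study.snp_ids, columns=study.snp_ids).to_csv(
            f"{prefix}_corr.tsv", sep="\t", index_label="snp_id"
        )
    return log
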