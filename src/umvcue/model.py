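"""Model/Results front end.

`TwoStageSelectionModel` bundles the ranked study data with the selection
rule that produced it; `fit()` computes every estimator for every rank and
returns a `TwoStageSelectionResults` carrying the estimate table,
diagnostics, a text `summary()`, and the bootstrap / sensitivity methods.

    >>> from umvcue import TwoStageSelectionModel, parkes_table1
    >>> res = TwoStageSelectionModel(parkes_table1()).fit()
    >>> res.estimates[["snp_id", "or_mle", "or_umvcue"]].head(2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, BootstrapSpec, bootstrap_ci
from .data import StudyData, write_estimates
from .estimators import estimate_all, umvcue
from .selection import SelectionRule, check_event


class TwoStageSelectionModel:
    """Conditional estimation model for ranked two-stage summary data.

    Parameters
    ----------
    study : StudyData
        Candidates in stage-1 rank order with the known stage-1 covariance.
    rule : SelectionRule, optional
        How stage 1 ranked (and thresholded) the candidates.  The observed
        data must satisfy the rule's selection event; this is verified at
        construction.
    """

    def __init__(self, study: StudyData, rule: SelectionRule | None = None):
        self.rule = rule if rule is not None else SelectionRule()
        self.study = check_event(study, self.rule)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        rule: SelectionRule | None = None,
        correlation: np.ndarray | None = None,
    ) -> "TwoStageSelectionModel":
        """Build from a DataFrame with columns snp_id, x, sigma, y, tau
        (log scale, stage-1 rank order) and an optional correlation matrix."""
        from .data import SnpSummary

        snps = tuple(
            SnpSummary(str(r.snp_id), float(r.x), float(r.sigma),
                       float(r.y), float(r.tau),
                       getattr(r, "region", None))
            for r in df.itertuples(index=False)
        )
        V = None
        if correlation is not None:
            sig = np.array([s.sigma for s in snps])
            V = np.asarray(correlation, dtype=float) * np.outer(sig, sig)
        return cls(StudyData(snps, V), rule)

    def fit(
        self, rho_spec: dict[tuple[str, str], float] | None = None
    ) -> "TwoStageSelectionResults":
        """Compute stage-2, MLE, independence-UMVCUE and UMVCUE estimates
        for every rank; ``rho_spec`` adds pair correlations on top of the
        study covariance."""
        study = self.study.with_correlations(rho_spec) if rho_spec else self.study
        table = estimate_all(study, self.rule)
        return TwoStageSelectionResults(model=self, study=study, estimates=table)


@dataclass(frozen=True)
class TwoStageSelectionResults:
    """Fitted estimate table plus bootstrap and sensitivity analyses."""

    model: TwoStageSelectionModel
    study: StudyData
    estimates: pd.DataFrame = field(repr=False)

    def summary(self, decimals: int = 2) -> str:
        """Human-readable per-rank table on the OR scale (rounded); use
        ``.estimates`` for full precision."""
        df = self.estimates
        view = pd.DataFrame(
            {
                "rank": df["rank"],
                "snp_id": df.snp_id,
                "region": df.region.fillna(""),
                "stage1": df.or_stage1.round(decimals),
                "stage2": df.or_stage2.round(decimals),
                "MLE": df.or_mle.round(decimals),
                "UMVCUE": df.or_umvcue.round(decimals),
                "UMVCUE(indep)": df.or_umvcue_indep.round(decimals),
            }
        )
        rule = self.model.rule
        head = (
            "Two-stage selection model: conditionally unbiased estimates\n"
            f"K = {self.study.K} candidates, ordering = {rule.ordering}, "
            f"p_crit = {rule.p_crit:g}\n"
            "Odds-ratio scale\n"
        )
        return head + view.to_string(index=False)

    def bootstrap_ci(
        self,
        pair: tuple[int, int],
        rho: float = 0.0,
        B: int = 10_000,
        alpha: float = 0.05,
        seed: int = 0,
        stage2_sd: str = "tau",
    ) -> BootstrapResult:
        """Parametric pair-bootstrap CIs (see :mod:`umvcue.bootstrap`)."""
        spec = BootstrapSpec(pair=pair, rho=rho, B=B, alpha=alpha, seed=seed,
                             stage2_sd=stage2_sd)
        return bootstrap_ci(spec, self.model.study, self.model.rule)

    def sweep_rho(self, pair: tuple[int, int], rhos) -> pd.DataFrame:
        """Sensitivity of the pair's UMVCUEs to the assumed correlation:
        one row per rho with both estimates on the OR scale."""
        j1, j2 = pair
        a = self.model.study.snp_ids[j1 - 1]
        b = self.model.study.snp_ids[j2 - 1]
        rows = []
        for rho in rhos:
            study = self.model.study.with_correlations({(a, b): float(rho)})
            u1 = umvcue(study, self.model.rule, j1, _checked=True).value
            u2 = umvcue(study, self.model.rule, j2, _checked=True).value
            rows.append(
                {"rho": float(rho), f"or_umvcue_{a}": math.exp(u1),
                 f"or_umvcue_{b}": math.exp(u2)}
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path, seed: int | None = None) -> None:
        rule = self.model.rule
        header = [
            f"ordering={rule.ordering} p_crit={rule.p_crit:g}",
            "scale=log and OR; quantile_convention=type7",
        ]
        if seed is not None:
            header.append(f"seed={seed}")
        write_estimates(self.estimates, path, header)
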