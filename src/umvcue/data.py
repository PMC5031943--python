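"""Two-stage summary-statistic containers and I/O.

Effects live on the natural-log odds-ratio scale everywhere inside the
package; odds ratios appear only at the I/O boundary.  Input tables may give
effects directly (``log`` dialect), as OR with confidence limits
(``or_ci``), or as 2x2 allele-count tables (``counts``).

The Crohn's disease replication data of Parkes et al. (2007) — the 11 SNPs
carried from the WTCCC scan into the replication cohort, as printed at 2 dp
— is bundled as :func:`parkes_table1`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .exceptions import InputError

logger = logging.getLogger(__name__)

_DIAG_REL_TOL = 1e-9


@dataclass(frozen=True)
class SnpSummary:
    """One candidate's two-stage summary on the log-OR scale.

    ``x``/``sigma`` are the stage-1 (scan) estimate and standard error,
    ``y``/``tau`` the stage-2 (replication) estimate and standard error.
    """

    snp_id: str
    x: float
    sigma: float
    y: float
    tau: float
    region: str | None = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.tau > 0):
            raise InputError(f"{self.snp_id}: standard errors must be positive")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"{self.snp_id}: effects must be finite")

    @property
    def z1(self) -> float:
        """Stage-1 two-sided z-score |x|/sigma."""
        return abs(self.x) / self.sigma


@dataclass(frozen=True)
class StudyData:
    """Ranked candidates plus the known stage-1 covariance matrix.

    ``snps`` is ordered by stage-1 rank (position 0 = rank 1).  ``V`` is the
    K x K covariance of the stage-1 log-OR estimates, assumed known (e.g.
    from external LD information); its diagonal must equal sigma_i^2.
    """

    snps: tuple[SnpSummary, ...]
    V: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        snps = tuple(self.snps)
        object.__setattr__(self, "snps", snps)
        if not snps:
            raise InputError("study has no candidates")
        if self.V is None:
            object.__setattr__(self, "V", np.diag(self.sigma**2))
        else:
            V = np.asarray(self.V, dtype=float)
            object.__setattr__(self, "V", V)
            _validate_cov(V, self.sigma, [s.snp_id for s in snps])

    # -- array views -------------------------------------------------------
    @property
    def K(self) -> int:
        return len(self.snps)

    @property
    def x(self) -> np.ndarray:
        return np.array([s.x for s in self.snps])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([s.sigma for s in self.snps])

    @property
    def y(self) -> np.ndarray:
        return np.array([s.y for s in self.snps])

    @property
    def tau(self) -> np.ndarray:
        return np.array([s.tau for s in self.snps])

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    # -- derived studies ----------------------------------------------------
    def with_correlations(self, rho: Mapping[tuple[str, str], float]) -> "StudyData":
        """Return a copy whose V adds off-diagonal terms rho*sigma_i*sigma_j
        for the named SNP pairs (all other off-diagonals kept)."""
        V = self.V.copy()
        ids = {s: i for i, s in enumerate(self.snp_ids)}
        sig = self.sigma
        for (a, b), r in rho.items():
            if a not in ids or b not in ids:
                raise InputError(f"unknown SNP pair ({a}, {b})")
            if not -1.0 < r < 1.0:
                raise InputError(f"correlation for ({a}, {b}) must be in (-1, 1)")
            i, j = ids[a], ids[b]
            V[i, j] = V[j, i] = r * sig[i] * sig[j]
        return StudyData(self.snps, V)

    def with_independence(self) -> "StudyData":
        """Copy with all off-diagonal covariance forced to zero."""
        return StudyData(self.snps, np.diag(self.sigma**2))

    def replace_snp(self, j: int, **changes) -> "StudyData":
        """Copy with fields of the rank-(j+1) candidate replaced (x/y only;
        SEs and V are unchanged)."""
        snps = list(self.snps)
        snps[j] = replace(snps[j], **changes)
        return StudyData(tuple(snps), self.V)


def _validate_cov(V: np.ndarray, sigma: np.ndarray, ids: Sequence[str]) -> None:
    K = len(sigma)
    if V.shape != (K, K):
        raise InputError(f"covariance is {V.shape}, expected ({K}, {K})")
    if not np.allclose(V, V.T, rtol=0, atol=1e-12 * max(1.0, float(np.abs(V).max()))):
        raise InputError("covariance matrix is not symmetric")
    d = np.diag(V)
    if not np.allclose(d, sigma**2, rtol=_DIAG_REL_TOL, atol=0):
        k = int(np.argmax(np.abs(d - sigma**2)))
        raise InputError(
            f"V[{k},{k}]={d[k]:.6g} disagrees with sigma_{ids[k]}^2={sigma[k] ** 2:.6g}"
        )
    corr = V / np.outer(sigma, sigma)
    off = corr[~np.eye(K, dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 1.0:
        raise InputError("implied correlations must be strictly inside (-1, 1)")
    try:
        np.linalg.cholesky(V)
    except np.linalg.LinAlgError as e:
        raise InputError("covariance matrix is not positive definite") from e


# ---------------------------------------------------------------------------
# scale conversions
# ---------------------------------------------------------------------------

def or_ci_to_log(
    or_point: float, ci_lo: float, ci_hi: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert an OR with a symmetric (on the log scale) CI to (log-OR, SE).

    SE = log-width / (2 z) with z the standard-normal (1+level)/2 quantile;
    asymmetry of printed, rounded CIs is deliberately ignored.
    """
    if not (or_point > 0 and ci_lo > 0 and ci_hi > 0):
        raise InputError("OR and CI limits must be positive")
    if not 0 < level < 1:
        raise InputError("confidence level must be in (0, 1)")
    if ci_lo == ci_hi:
        raise InputError("degenerate CI: lower and upper limits coincide")
    if not (ci_lo <= or_point <= ci_hi):
        raise InputError(
            f"point estimate {or_point} outside its CI ({ci_lo}, {ci_hi})"
        )
    z = ndtri(0.5 + level / 2.0)
    return math.log(or_point), (math.log(ci_hi) - math.log(ci_lo)) / (2.0 * z)


def log_to_or_ci(
    effect: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Inverse of :func:`or_ci_to_log` (round-trips exactly)."""
    z = ndtri(0.5 + level / 2.0)
    return math.exp(effect), math.exp(effect - z * se), math.exp(effect + z * se)


def counts_to_log(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Log odds ratio ln(ad/bc) with Woolf SE sqrt(1/a+1/b+1/c+1/d).

    Zero cells are refused outright: choose a continuity correction yourself
    (or supply OR/CI) rather than have one applied silently.
    """
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise InputError("allele counts must be non-negative")
    if any(v == 0 for v in cells):
        raise InputError(
            "zero cell in 2x2 table: supply an OR/CI instead, or apply your "
            "own continuity correction (none is applied silently)"
        )
    return math.log(a * d / (b * c)), math.sqrt(sum(1.0 / v for v in cells))


# ---------------------------------------------------------------------------
# table reading
# ---------------------------------------------------------------------------

_DIALECT_COLS = {
    "log": ["snp_id", "x", "sigma", "y", "tau"],
    "or_ci": ["snp_id", "or1", "lo1", "hi1", "or2", "lo2", "hi2"],
    "counts": ["snp_id", "a1", "b1", "c1", "d1", "a2", "b2", "c2", "d2"],
}


def read_summary_table(
    path: str | Path,
    dialect: str = "log",
    level: float = 0.95,
    correlation: str | Path | None = None,
) -> StudyData:
    """Read a TSV of two-stage summaries (rows in stage-1 rank order).

    ``correlation`` optionally names a correlation-matrix file (square with
    snp_id header row/column, or long format snp_a/snp_b/rho); correlations
    are scaled by sigma_i*sigma_j into a covariance.  Without one, stage-1
    estimates are treated as independent — loudly.
    """
    if dialect not in _DIALECT_COLS:
        raise InputError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECT_COLS)}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DIALECT_COLS[dialect] if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing} for dialect {dialect!r}")
    if df.empty:
        raise InputError(f"{path}: table has no rows")

    snps = []
    for _, row in df.iterrows():
        region = str(row["region"]) if "region" in df.columns and pd.notna(row.get("region")) else None
        if dialect == "log":
            s = SnpSummary(str(row.snp_id), float(row.x), float(row.sigma),
                           float(row.y), float(row.tau), region)
        elif dialect == "or_ci":
            x, sig = or_ci_to_log(row.or1, row.lo1, row.hi1, level)
            y, tau = or_ci_to_log(row.or2, row.lo2, row.hi2, level)
            s = SnpSummary(str(row.snp_id), x, sig, y, tau, region)
        else:
            x, sig = counts_to_log(row.a1, row.b1, row.c1, row.d1)
            y, tau = counts_to_log(row.a2, row.b2, row.c2, row.d2)
            s = SnpSummary(str(row.snp_id), x, sig, y, tau, region)
        snps.append(s)

    study = StudyData(tuple(snps))
    if correlation is not None:
        corr = read_correlation(correlation, study.snp_ids)
        sig = study.sigma
        study = StudyData(study.snps, corr * np.outer(sig, sig))
    else:
        logger.warning(
            "no correlation source supplied: assuming independent stage-1 "
            "estimates (V = diag(sigma^2))"
        )
    return study


def read_correlation(path: str | Path, snp_ids: Sequence[str]) -> np.ndarray:
    """Read a stage-1 correlation matrix (square or long TSV); unit diagonal."""
    df = pd.read_csv(path, sep="\t")
    K = len(snp_ids)
    idx = {s: i for i, s in enumerate(snp_ids)}
    corr = np.eye(K)
    if set(df.columns[:3]) >= {"snp_a", "snp_b", "rho"}:
        for _, row in df.iterrows():
            a, b = str(row.snp_a), str(row.snp_b)
            if a not in idx or b not in idx:
                raise InputError(f"correlation file names unknown SNP pair ({a}, {b})")
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = float(row.rho)
    else:
        first = df.columns[0]
        rows = [str(v) for v in df[first]]
        cols = [str(c) for c in df.columns[1:]]
        if set(rows) != set(snp_ids) or set(cols) != set(snp_ids):
            raise InputError("square correlation file must be indexed by the study's snp_ids")
        sub = df.set_index(first)
        for a in snp_ids:
            for b in snp_ids:
                corr[idx[a], idx[b]] = float(sub.loc[a, b])
    off = corr[~np.eye(K, dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 1.0:
        raise InputError("off-diagonal correlations must be strictly inside (-1, 1)")
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise InputError("correlation matrix is not positive definite") from e
    return corr


def write_estimates(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write an estimate table as TSV, with optional '#' header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bundled fixture: Parkes et al. (2007) Crohn's disease replication
# ---------------------------------------------------------------------------

# (snp_id, region, stage-1 OR, lo, hi, stage-2 OR, lo, hi), printed at 2 dp,
# in stage-1 significance rank order; rs6887695 excluded (its scan
# significance did not survive data cleaning).
_PARKES_ROWS = (
    ("rs17234657", "5p13", 1.55, 1.38, 1.74, 1.16, 1.00, 1.35),
    ("rs9292777", "5p13", 1.38, 1.26, 1.51, 1.34, 1.20, 1.50),
    ("rs10883365", "10q24", 1.27, 1.17, 1.38, 1.18, 1.05, 1.32),
    ("rs2542151", "18p11", 1.35, 1.21, 1.50, 1.15, 1.00, 1.32),
    ("rs13361189", "5q33", 1.51, 1.30, 1.76, 1.38, 1.15, 1.66),
    ("rs9858542", "3p21", 1.26, 1.15, 1.38, 1.17, 1.04, 1.31),
    ("rs4958847", "5q33", 1.35, 1.20, 1.53, 1.36, 1.17, 1.59),
    ("rs10077785", "5q23", 1.29, 1.16, 1.43, 1.19, 1.05, 1.36),
    ("rs12035082", "1q24", 1.22, 1.12, 1.33, 1.14, 1.02, 1.27),
    ("rs2836754", "21q22", 1.22, 1.12, 1.33, 1.15, 1.03, 1.28),
    ("rs10801047", "1q31", 1.38, 1.18, 1.61, 1.47, 1.22, 1.76),
)

#: SNP pairs sharing a chromosomal region, with the empirical genotype
#: correlations measured in 498 Europeans of the 1000 Genomes project.
#: Used only as sensitivity-analysis inputs, never as defaults.
PARKES_REGION_PAIRS = {
    ("rs17234657", "rs9292777"): -0.28,  # 5p13
    ("rs13361189", "rs4958847"): 0.78,  # 5q33
}


def parkes_table1(
    rho: Mapping[tuple[str, str], float] | None = None, level: float = 0.95
) -> StudyData:
    """The 11-SNP Crohn's disease two-stage dataset (log scale).

    By default the stage-1 estimates are treated as independent (identity
    correlation); pass ``rho`` to correlate same-region pairs, e.g.
    ``{("rs17234657", "rs9292777"): 0.88}``.
    """
    snps = []
    for sid, region, o1, l1, h1, o2, l2, h2 in _PARKES_ROWS:
        x, sig = or_ci_to_log(o1, l1, h1, level)
        y, tau = or_ci_to_log(o2, l2, h2, level)
        snps.append(SnpSummary(sid, x, sig, y, tau, region))
    study = StudyData(tuple(snps))
    if rho:
        study = study.with_correlations(rho)
    return study
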