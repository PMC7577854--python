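"""P-value-threshold polygenic scores and prediction regressions.

A score at threshold t is sum over base-GWAS SNPs with p <= t of
beta_j * dosage_j, oriented to the base effect allele after matching
alleles between base and target; scores are standardized before use.
No LD clumping is applied by default (the synthetic SNP panel is
near-independent across LD blocks); optional greedy clumping is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import GwasSummaryStats, residualize
from .simulate import GenotypeMatrix

__all__ = ["PrsResult", "compute_prs", "prs_regression", "clump"]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.5, 1.0)
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

log = logging.getLogger(__name__)


@dataclass
class PrsResult:
    threshold: float
    n_snps_included: int
    beta: float
    se: float
    p: float
    r2_increment: float


def _match_alleles(base: pd.DataFrame, target: GenotypeMatrix):
    """Align base effect alleles with target dosage orientation.

    Returns (target column indices, orientation sign, base rows) for the
    SNP intersection; strand-ambiguous SNPs are removed.
    """
    tidx = {s: j for j, s in enumerate(target.snp_ids)}
    cols, signs, rows = [], [], []
    n_ambiguous = 0
    n_mismatch = 0
    for row in base.itertuples(index=False):
        j = tidx.get(row.SNP)
        if j is None:
            continue
        if (row.A1, row.A2) in _AMBIGUOUS:
            n_ambiguous += 1
            continue
        ta1, ta2 = target.a1[j], target.a2[j]
        if (row.A1, row.A2) == (ta1, ta2):
            sign = 1.0
        elif (row.A1, row.A2) == (ta2, ta1):
            sign = -1.0
        else:
            n_mismatch += 1
            continue
        cols.append(j)
        signs.append(sign)
        rows.append(row)
    if n_ambiguous:
        log.info("compute_prs: removed %d strand-ambiguous SNPs", n_ambiguous)
    if n_mismatch:
        log.info("compute_prs: removed %d allele-mismatched SNPs", n_mismatch)
    if not cols:
        raise ValueError("no allele-matched SNPs shared between base and target")
    return np.asarray(cols), np.asarray(signs), pd.DataFrame(rows)


def compute_prs(
    base: GwasSummaryStats,
    target: GenotypeMatrix,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """N x T table of standardized scores, one column per p-value cutoff.

    A threshold admitting zero SNPs yields a zero column (flagged in logs).
    """
    thresholds = sorted(thresholds)
    cols, signs, rows = _match_alleles(base.table, target)
    betas = rows["BETA"].to_numpy()
    pvals = rows["P"].to_numpy()
    # dosages re-oriented to count the base effect allele
    D = target.dosages[:, cols].astype(np.float32)
    D = np.where(signs < 0, 2.0 - D, D)
    out = {}
    for t in thresholds:
        mask = pvals <= t
        if not mask.any():
            log.warning("compute_prs: zero SNPs at threshold %g", t)
            out[t] = np.zeros(target.n_individuals)
            continue
        score = D[:, mask] @ betas[mask].astype(np.float32)
        sd = score.std()
        out[t] = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    table = pd.DataFrame(out, index=np.arange(target.n_individuals))
    table.columns.name = "p_threshold"
    return table


def prs_regression(
    prs: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    threshold: float = np.nan,
    n_snps: int = 0,
) -> PrsResult:
    """OLS of a (pre-residualized) phenotype on a standardized score.

    ``r2_increment`` is R2(covariates + PRS) - R2(covariates); with a
    pre-residualized phenotype and no remaining covariates this equals the
    squared PRS-phenotype correlation.
    """
    s = np.asarray(prs, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if s.std() == 0:
        raise ValueError("constant polygenic score")
    if covariates is not None and covariates.shape[1] > 0:
        y = residualize(y, covariates)
        s_res = residualize(s, covariates)
    else:
        y = (y - y.mean()) / y.std()
        s_res = (s - s.mean()) / s.std()
    n = len(y)
    beta = float(np.mean(s_res * y))  # both standardized
    resid_var = max(1.0 - beta**2, 1e-30)
    se = float(np.sqrt(resid_var * n / (n - 2) / n))
    z = beta / se
    p = float(2.0 * stats.t.sf(abs(z), df=n - 2))
    return PrsResult(
        threshold=threshold,
        n_snps_included=n_snps,
        beta=beta,
        se=se,
        p=p,
        r2_increment=float(beta**2),
    )


def predict_all_thresholds(
    base: GwasSummaryStats,
    target: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> list:
    """Score the target cohort and fit the prediction regression per cutoff."""
    scores = compute_prs(base, target, thresholds)
    pvals = base.table["P"].to_numpy()
    results = []
    for t in scores.columns:
        results.append(
            prs_regression(
                scores[t].to_numpy(),
                phenotype,
                covariates,
                threshold=float(t),
                n_snps=int((pvals <= t).sum()),
            )
        )
    return results


def clump(
    sumstats: GwasSummaryStats,
    ld,
    r2: float = 0.1,
    window_kb: float = 250.0,
) -> GwasSummaryStats:
    """Greedy LD clumping by ascending p (optional; PRSice-style)."""
    table = sumstats.table
    chrom = table["CHR"].to_numpy()
    bp = table["BP"].to_numpy()
    snp = table["SNP"].to_numpy()
    p = table["P"].to_numpy()
    kept: list[int] = []
    for i in np.lexsort((bp, chrom, p)):
        if all(
            chrom[i] != chrom[j]
            or abs(float(bp[i]) - float(bp[j])) > window_kb * 1000.0
            or ld.r2(snp[i], snp[j]) < r2
            for j in kept
        ):
            kept.append(i)
    kept = sorted(kept)
    return GwasSummaryStats(table=table.iloc[kept].reset_index(drop=True), trait=sumstats.trait)
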