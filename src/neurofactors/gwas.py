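"""Per-SNP additive-model association on residualized factor scores.

Phenotypes are pre-residualized on covariates (OLS), standardized, and each
SNP is tested by closed-form simple linear regression — the behaviour of a
linear GWAS tool run on covariate-adjusted phenotypes.  P-values use the
normal tail (samples are large).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = ["GwasSummaryStats", "residualize", "filter_snps", "run_gwas"]


@dataclass
class GwasSummaryStats:
    """Per-SNP association records for one trait, as a DataFrame.

    Columns: SNP CHR BP A1 A2 FREQ BETA SE Z P N.
    """

    table: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        required = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "Z", "P", "N"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")

    def __len__(self) -> int:
        return len(self.table)


def residualize(scores, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of each score column on the covariate design, standardized.

    Categorical covariate columns are one-hot encoded (first level dropped);
    an intercept is always included.  Raises on a rank-deficient design,
    naming the collinear columns.
    """
    Y = np.asarray(getattr(scores, "scores", scores), dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X, names = _design_matrix(covariates, len(Y))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    resid = (resid - resid.mean(axis=0)) / resid.std(axis=0)
    return resid if resid.shape[1] > 1 else resid[:, 0]


def _design_matrix(covariates: pd.DataFrame, n: int):
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["intercept"]
    enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(enc)), enc.to_numpy(dtype=float)])
    return X, ["intercept"] + list(enc.columns)


def _collinear_columns(X: np.ndarray, names) -> list:
    bad = []
    kept = [0]
    for j in range(1, X.shape[1]):
        sub = X[:, kept + [j]]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            bad.append(names[j])
        else:
            kept.append(j)
    return bad


def filter_snps(
    genotypes: GenotypeMatrix, maf_min: float = 0.0, info_min: float = 0.0,
    info: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Drop SNPs below a MAF or imputation-quality threshold.

    Synthetic genotypes are hard calls, so ``info`` defaults to 1 for every
    SNP unless supplied.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= info_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = genotypes.maf >= maf_min
    if info is not None:
        keep &= np.asarray(info) >= info_min
    if not keep.any():
        raise ValueError("all SNPs removed by MAF/info filters")
    return genotypes.subset(keep)


def run_gwas(
    genotypes: GenotypeMatrix, phenotype: np.ndarray, trait: str = ""
) -> GwasSummaryStats:
    """Closed-form per-SNP simple regression of a standardized phenotype.

    beta_j = cov(g_j, y) / var(g_j); SE from the residual variance with
    n - 2 degrees of freedom; identical to per-SNP OLS.  Zero-variance SNPs
    are excluded.
    """
    return run_gwas_multi(genotypes, phenotype, traits=(trait,))[0]


def run_gwas_multi(
    genotypes: GenotypeMatrix, phenotypes: np.ndarray, traits=None
) -> list:
    """``run_gwas`` for one or more phenotype columns in a single pass."""
    Y = np.asarray(phenotypes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = genotypes.n_individuals
    if Y.shape[0] != n:
        raise ValueError("phenotype length does not match genotypes")
    K = Y.shape[1]
    if traits is None:
        traits = [""] * K
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)

    G = genotypes.dosages
    # dosage moments from {0,1,2} counts (avoids a float copy of G)
    n1 = (G == 1).sum(axis=0)
    n2 = (G == 2).sum(axis=0)
    gmean = (n1 + 2.0 * n2) / n
    gvar = (n1 + 4.0 * n2) / n - gmean**2
    ok = gvar > 0
    if not ok.all():
        import logging

        logging.getLogger(__name__).info(
            "run_gwas: excluded %d zero-variance SNPs", int((~ok).sum())
        )
    # cov(g, y) in float64, chunked over SNPs to bound memory
    M = genotypes.n_snps
    cross = np.empty((M, K))
    step = 2048
    for j0 in range(0, M, step):
        j1 = min(j0 + step, M)
        cross[j0:j1] = G[:, j0:j1].astype(np.float64).T @ Y
    out = []
    for k in range(K):
        cov = cross[:, k] / n  # Y column is mean-centered
        beta = np.full(M, np.nan)
        se = np.full(M, np.nan)
        beta[ok] = cov[ok] / gvar[ok]
        # residual variance: var(y) - beta^2 var(g), with n-2 df
        rss = np.clip(1.0 - beta[ok] ** 2 * gvar[ok], 1e-30, None) * n
        se[ok] = np.sqrt(rss / (n - 2) / (n * gvar[ok]))
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        table = pd.DataFrame(
            {
                "SNP": genotypes.snp_ids,
                "CHR": genotypes.chrom,
                "BP": genotypes.bp,
                "A1": genotypes.a1,
                "A2": genotypes.a2,
                "FREQ": genotypes.freq_a1,
                "BETA": beta,
                "SE": se,
                "Z": z,
                "P": p,
                "N": n,
            }
        )
        out.append(GwasSummaryStats(table=table[ok].reset_index(drop=True), trait=traits[k]))
    return out
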