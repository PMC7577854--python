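"""LD-score regression: LD scores, SNP heritability, genetic correlation.

Univariate model: E[chi2_j] = intercept + n * h2 * l_j / M, fitted by
weighted least squares with the standard two-component LDSC weights
(heteroskedasticity x over-counting), iterated once from an initial
unweighted fit.  Bivariate model: E[z_a z_b] = intercept + n * cov_g * l_j / M;
rg = cov_g / sqrt(h2_a * h2_b).  Standard errors come from a delete-one
block jackknife over contiguous SNP blocks.

Filters follow the analysis this package reproduces: SNPs with chi2 > 80
and MAF < 0.01 are removed before regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import GwasSummaryStats
from .simulate import GenotypeMatrix

__all__ = [
    "LDScoreTable",
    "LdscFit",
    "compute_ld_scores",
    "h2_regression",
    "rg_regression",
    "bh_fdr",
]

DEFAULT_N_BLOCKS = 200
CHI2_MAX = 80.0
MAF_MIN = 0.01


@dataclass
class LDScoreTable:
    """Per-SNP LD scores (CHR SNP BP L2) plus the total SNP count M."""

    table: pd.DataFrame
    M: int

    def __post_init__(self) -> None:
        missing = [c for c in ("SNP", "CHR", "BP", "L2") if c not in self.table.columns]
        if missing:
            raise ValueError(f"LD score table missing columns {missing}")


@dataclass
class LdscFit:
    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_blocks: int
    snps_used: int
    filters_applied: dict = field(default_factory=dict)
    kind: str = "h2"
    # heritability used inside the heteroskedasticity weights (from the
    # initial unweighted fit); rg_regression reuses it so that a trait
    # regressed on itself gives genetic covariance == h2 exactly
    weight_h2: float = 0.0


def compute_ld_scores(
    genotypes: GenotypeMatrix, window_kb: float = 1000.0, chunk: int = 256
) -> LDScoreTable:
    """l_j = sum over SNPs within the window of adjusted r^2 with SNP j.

    r2_adj = r2 - (1 - r2) / (n - 2), the usual unbiasing adjustment; the
    self-pair (r2 = 1) is included, so l_j >= 1.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    n = genotypes.n_individuals
    window_bp = window_kb * 1000.0
    l2 = np.empty(genotypes.n_snps)
    for c in np.unique(genotypes.chrom):
        idx = np.nonzero(genotypes.chrom == c)[0]
        bp = genotypes.bp[idx].astype(float)
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"bp not strictly increasing on chromosome {c}")
        X = genotypes.subset(idx).standardized(dtype=np.float32)
        m_c = len(idx)
        for a in range(0, m_c, chunk):
            b = min(a + chunk, m_c)
            lo = int(np.searchsorted(bp, bp[a] - window_bp, side="left"))
            hi = int(np.searchsorted(bp, bp[b - 1] + window_bp, side="right"))
            R = (X[:, a:b].T @ X[:, lo:hi]) / np.float32(n)
            r2 = (R.astype(np.float64)) ** 2
            adj = r2 - (1.0 - r2) / (n - 2)
            in_window = (
                np.abs(bp[None, lo:hi] - bp[a:b, None]) <= window_bp
            )
            l2[idx[a:b]] = np.where(in_window, adj, 0.0).sum(axis=1)
    table = pd.DataFrame(
        {
            "CHR": genotypes.chrom,
            "SNP": genotypes.snp_ids,
            "BP": genotypes.bp,
            "L2": l2,
        }
    )
    return LDScoreTable(table=table, M=genotypes.n_snps)


# ---------------------------------------------------------------------------
# weighted regression with block jackknife


def _wls_blocks(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """Weighted LS of y on (1, x) plus delete-one-block estimates.

    Returns (coef, delete_one) where coef = (intercept, slope) and
    delete_one has shape (n_blocks, 2).  Weights stay fixed across blocks,
    matching the reference jackknife.
    """
    m = len(x)
    if m < n_blocks:
        raise ValueError(f"fewer SNPs ({m}) than jackknife blocks ({n_blocks})")
    if np.std(x) == 0:
        raise ValueError("no variation in LD scores: slope is undefined")
    X = np.column_stack([np.ones(m), x])
    Xw = X * w[:, None]
    A = X.T @ Xw
    v = Xw.T @ y
    coef = np.linalg.solve(A, v)
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    delete_one = np.empty((n_blocks, 2))
    for i in range(n_blocks):
        sl = slice(bounds[i], bounds[i + 1])
        Ai = X[sl].T @ Xw[sl]
        vi = Xw[sl].T @ y[sl]
        delete_one[i] = np.linalg.solve(A - Ai, v - vi)
    return coef, delete_one


def _jackknife_se(delete_one: np.ndarray) -> np.ndarray:
    b = delete_one.shape[0]
    mean = delete_one.mean(axis=0)
    return np.sqrt((b - 1) / b * np.sum((delete_one - mean) ** 2, axis=0))


def _apply_filters(table: pd.DataFrame, chi2_max: float, maf_min: float):
    chi2 = table["Z"].to_numpy() ** 2
    maf = np.minimum(table["FREQ"].to_numpy(), 1.0 - table["FREQ"].to_numpy())
    keep = (chi2 <= chi2_max) & (maf >= maf_min)
    filters = {
        "chi2_max": chi2_max,
        "maf_min": maf_min,
        "removed_chi2": int((chi2 > chi2_max).sum()),
        "removed_maf": int((maf < maf_min).sum()),
    }
    return table[keep].reset_index(drop=True), filters


def _merge(sumstats: GwasSummaryStats, ldscores: LDScoreTable) -> pd.DataFrame:
    merged = sumstats.table.merge(
        ldscores.table[["SNP", "L2"]], on="SNP", how="inner"
    )
    if merged.empty:
        raise ValueError("no SNPs shared between summary statistics and LD scores")
    return merged


def h2_regression(
    sumstats: GwasSummaryStats,
    ldscores: LDScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    chi2_max: float = CHI2_MAX,
    maf_min: float = MAF_MIN,
) -> LdscFit:
    """Univariate LD-score regression for SNP heritability."""
    merged = _merge(sumstats, ldscores)
    merged, filters = _apply_filters(merged, chi2_max, maf_min)
    n = float(merged["N"].iloc[0])
    M = ldscores.M
    ell = np.clip(merged["L2"].to_numpy(), 1.0, None)
    x = n * ell / M
    y = merged["Z"].to_numpy() ** 2
    # step 1: unweighted fit for an initial heritability guess
    (_, slope0), _ = _wls_blocks(x, y, np.ones_like(x), n_blocks)
    h2_0 = float(np.clip(slope0, 0.0, 1.0))
    # step 2: two-component weights (heteroskedasticity x over-counting),
    # one iteration from the unweighted fit
    w = 1.0 / (ell * (1.0 + n * h2_0 * ell / M) ** 2)
    coef, d1 = _wls_blocks(x, y, w, n_blocks)
    se = _jackknife_se(d1)
    return LdscFit(
        h2=float(coef[1]),
        intercept=float(coef[0]),
        se_h2=float(se[1]),
        se_intercept=float(se[0]),
        n_blocks=n_blocks,
        snps_used=len(merged),
        filters_applied=filters,
        kind="h2",
        weight_h2=h2_0,
    )


def rg_regression(
    sumstats_a: GwasSummaryStats,
    sumstats_b: GwasSummaryStats,
    ldscores: LDScoreTable,
    h2_a: LdscFit,
    h2_b: LdscFit,
    n_blocks: int = DEFAULT_N_BLOCKS,
    chi2_max: float = CHI2_MAX,
    maf_min: float = MAF_MIN,
    min_snps: int = 1000,
) -> dict:
    """Bivariate LD-score regression for the genetic correlation.

    The intercept is left free (shared samples inflate E[z_a z_b] by a
    constant).  The jackknife resamples the full ratio
    cov_g / sqrt(h2_a h2_b), re-estimating all three slopes per block.
    """
    if h2_a.h2 <= 0 or h2_b.h2 <= 0:
        raise ValueError(
            "rg undefined: non-positive heritability "
            f"(h2_a={h2_a.h2:.4g}, h2_b={h2_b.h2:.4g})"
        )
    merged = sumstats_a.table.merge(
        sumstats_b.table[["SNP", "Z", "FREQ"]], on="SNP", suffixes=("", "_b")
    ).merge(ldscores.table[["SNP", "L2"]], on="SNP")
    if len(merged) < min_snps:
        raise ValueError(f"only {len(merged)} overlapping SNPs (< {min_snps})")
    chi2_ok = (merged["Z"] ** 2 <= chi2_max) & (merged["Z_b"] ** 2 <= chi2_max)
    maf = np.minimum(merged["FREQ"], 1.0 - merged["FREQ"])
    merged = merged[chi2_ok & (maf >= maf_min)].reset_index(drop=True)

    n = float(merged["N"].iloc[0])
    M = ldscores.M
    ell = np.clip(merged["L2"].to_numpy(), 1.0, None)
    x = n * ell / M
    za = merged["Z"].to_numpy()
    zb = merged["Z_b"].to_numpy()

    # same weight recipe as h2_regression (via weight_h2), so a trait
    # regressed on itself reproduces its own h2 slope exactly
    w_het = (1.0 + n * h2_a.weight_h2 * ell / M) * (1.0 + n * h2_b.weight_h2 * ell / M)
    w = 1.0 / (ell * w_het)
    coef_ab, d1_ab = _wls_blocks(x, za * zb, w, n_blocks)
    wa = 1.0 / (ell * (1.0 + n * h2_a.weight_h2 * ell / M) ** 2)
    wb = 1.0 / (ell * (1.0 + n * h2_b.weight_h2 * ell / M) ** 2)
    _, d1_a = _wls_blocks(x, za**2, wa, n_blocks)
    _, d1_b = _wls_blocks(x, zb**2, wb, n_blocks)

    gcov = float(coef_ab[1])
    rg = gcov / np.sqrt(h2_a.h2 * h2_b.h2)
    denom = np.sqrt(np.clip(d1_a[:, 1], 1e-12, None) * np.clip(d1_b[:, 1], 1e-12, None))
    rg_d1 = d1_ab[:, 1] / denom
    se = float(_jackknife_se(rg_d1[:, None])[0])
    z = rg / se if se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {
        "rg": float(rg),
        "gcov": gcov,
        "intercept": float(coef_ab[0]),
        "se": se,
        "p": p,
        "snps_used": len(merged),
    }


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up: significance flags and adjusted p-values.

    adjusted p_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    significant = adjusted <= q
    return significant, adjusted
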