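"""Tetrachoric correlation of binary items.

Two-step maximum likelihood: item thresholds are fixed at the inverse-normal
of the observed margins, then the latent bivariate-normal correlation of
each item pair is found by 1-D likelihood optimisation over the four orthant
probabilities.  The bivariate-normal CDF uses the single-integral reduction
(integrating the correlation parameter) evaluated by adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "PolychoricResult",
    "estimate_thresholds",
    "tetrachoric_pair",
    "tetrachoric_matrix",
    "bvn_cdf",
    "nearest_psd",
]

RHO_CAP = 0.999
BVN_ABSTOL = 1e-10
OPT_XTOL = 1e-8


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses Phi2(h, k, rho) = Phi(h) Phi(k) + integral_0^rho phi2(h, k; r) dr,
    where phi2 is the bivariate normal density at (h, k).
    """
    if not np.isfinite(h) or not np.isfinite(k):
        if h == -np.inf or k == -np.inf:
            return 0.0
        if h == np.inf:
            return float(stats.norm.cdf(k))
        if k == np.inf:
            return float(stats.norm.cdf(h))
    if rho == 0.0:
        return float(stats.norm.cdf(h) * stats.norm.cdf(k))

    def dens(r: float) -> float:
        om = 1.0 - r * r
        return np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * om)) / (
            2.0 * np.pi * np.sqrt(om)
        )

    corr_term, _ = integrate.quad(dens, 0.0, rho, epsabs=BVN_ABSTOL, limit=200)
    return float(stats.norm.cdf(h) * stats.norm.cdf(k) + corr_term)


def estimate_thresholds(responses) -> np.ndarray:
    """Per-item liability thresholds: inverse-normal of the proportion of 0s.

    Raises for any item answered identically by the whole sample, naming it.
    """
    R = _as_matrix(responses)
    labels = _labels(responses, R.shape[1])
    p0 = (R == 0).mean(axis=0)
    constant = np.nonzero((p0 == 0.0) | (p0 == 1.0))[0]
    if constant.size:
        names = [labels[i] for i in constant]
        raise ValueError(f"items constant across the sample: {names}")
    return stats.norm.ppf(p0)


def tetrachoric_pair(
    item_a: np.ndarray, item_b: np.ndarray, thresholds: tuple[float, float] | None = None
) -> tuple[float, bool]:
    """ML tetrachoric correlation of two binary vectors.

    Returns ``(rho, boundary_flag)``; the flag marks an empty contingency
    cell, where the ML estimate sits at the |rho| = RHO_CAP boundary.
    """
    a = np.asarray(item_a).astype(np.int64)
    b = np.asarray(item_b).astype(np.int64)
    n = len(a)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & (1 - b)))
    n01 = int(np.sum((1 - a) & b))
    n00 = n - n11 - n10 - n01
    if min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0:
        raise ValueError("contingency table has an empty margin")
    if thresholds is None:
        t_a = float(stats.norm.ppf((n00 + n01) / n))
        t_b = float(stats.norm.ppf((n00 + n10) / n))
    else:
        t_a, t_b = thresholds

    return _pair_from_counts(n00, n01, n10, n11, t_a, t_b)


def nearest_psd(corr: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest-PSD correlation, rescaled to unit diagonal."""
    w, V = np.linalg.eigh(corr)
    w = np.clip(w, eig_floor, None)
    fixed = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class PolychoricResult:
    """Tetrachoric correlation matrix, thresholds and diagnostics."""

    corr: np.ndarray
    thresholds: np.ndarray
    n_used: int
    min_eigenvalue: float
    corr_psd: np.ndarray            # nearest-PSD copy (== corr when PSD)
    boundary_pairs: list = field(default_factory=list)
    item_labels: tuple = ()

    @property
    def is_psd(self) -> bool:
        return self.min_eigenvalue >= -1e-10


def tetrachoric_matrix(responses) -> PolychoricResult:
    """Pairwise tetrachoric correlation matrix of a binary item table."""
    R = _as_matrix(responses)
    labels = _labels(responses, R.shape[1])
    n, p = R.shape
    thresholds = estimate_thresholds(R)
    corr = np.eye(p)
    boundary_pairs = []
    # contingency counts for all pairs at once
    R64 = R.astype(np.int64)
    N11 = R64.T @ R64
    ones = R64.sum(axis=0)
    for i in range(p):
        for j in range(i + 1, p):
            n11 = N11[i, j]
            n10 = ones[i] - n11
            n01 = ones[j] - n11
            n00 = n - n11 - n10 - n01
            rho, flag = _pair_from_counts(
                n00, n01, n10, n11, thresholds[i], thresholds[j]
            )
            corr[i, j] = corr[j, i] = rho
            if flag:
                boundary_pairs.append((labels[i], labels[j]))
    min_eig = float(np.linalg.eigvalsh(corr).min())
    corr_psd = corr if min_eig >= -1e-10 else nearest_psd(corr)
    return PolychoricResult(
        corr=corr,
        thresholds=thresholds,
        n_used=n,
        min_eigenvalue=min_eig,
        corr_psd=corr_psd,
        boundary_pairs=boundary_pairs,
        item_labels=tuple(labels),
    )


def _pair_from_counts(n00, n01, n10, n11, t_a, t_b) -> tuple[float, bool]:
    counts = np.array([n00, n01, n10, n11], dtype=float)
    boundary = bool(np.any(counts == 0))
    if n01 == 0 and n10 == 0:
        return 1.0, boundary  # identical columns
    if n00 == 0 and n11 == 0:
        return -1.0, boundary

    def negloglik(rho: float) -> float:
        p00 = bvn_cdf(t_a, t_b, rho)
        pa0 = stats.norm.cdf(t_a)
        pb0 = stats.norm.cdf(t_b)
        probs = np.clip(
            [p00, pa0 - p00, pb0 - p00, 1.0 - pa0 - pb0 + p00], 1e-300, None
        )
        return -float(counts @ np.log(probs))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-RHO_CAP, RHO_CAP), method="bounded",
        options={"xatol": OPT_XTOL},
    )
    return float(res.x), boundary


def _as_matrix(responses) -> np.ndarray:
    R = getattr(responses, "responses", responses)
    R = np.asarray(R)
    if R.ndim != 2:
        raise ValueError("responses must be a 2-D binary table")
    if not np.isin(R, (0, 1)).all():
        raise ValueError("responses must contain only 0/1")
    return R


def _labels(responses, p: int):
    labels = getattr(responses, "item_labels", None)
    if labels is None or len(labels) != p:
        labels = tuple(f"item{i + 1}" for i in range(p))
    return labels
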