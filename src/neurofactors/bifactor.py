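"""Exploratory bifactor analysis with oblique Geomin rotation.

Pipeline: minimum-residual (ULS) extraction of k factors from a (tetrachoric)
correlation matrix, then gradient-projection rotation minimising the Geomin
criterion applied to the k-1 special columns only, on a partially oblique
manifold where the general factor is kept orthogonal to the specials (the
model constraint) while the specials are free to correlate.

The Geomin criterion for a q-column block of loadings is

    sum_i ( prod_r (lambda_ir^2 + eps) )^(1/q)

which is smallest when each item loads on a single column.  The fitting
default eps = 1e-4 is deliberately small: with a sizeable eps (e.g. the
textbook 0.01) the criterion's optimum on exact-bifactor populations with
correlated specials is visibly displaced toward a collapsed solution in
which the general factor absorbs part of the special-factor correlation —
see the methods note.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "BifactorModel",
    "FactorScores",
    "extract_unrotated",
    "geomin_criterion",
    "bifactor_geomin_rotate",
    "fit_indices",
    "factor_scores",
    "congruence",
    "fit_bifactor",
]

DEFAULT_EPSILON = 1e-4  # fitting default; see methods note on epsilon and factor collapse
DEFAULT_N_STARTS = 30
ROTATION_TOL = 1e-8
MAX_GP_ITER = 2000


@dataclass
class BifactorModel:
    """Fitted bifactor measurement model.

    Column 1 of ``loadings`` is the general factor; columns 2..k are the
    special factors.  ``phi`` has exact zeros between the general factor and
    each special factor (a model constraint, not an estimate).
    """

    loadings: np.ndarray
    phi: np.ndarray
    thresholds: np.ndarray | None = None
    uniqueness: np.ndarray | None = None
    fit: dict = field(default_factory=dict)
    variance_explained: np.ndarray | None = None
    criterion_value: float = np.nan
    rotation_meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def implied_corr(self) -> np.ndarray:
        """Model-implied correlation: Lambda Phi Lambda' + diag(uniqueness)."""
        R = self.loadings @ self.phi @ self.loadings.T
        uniq = self.uniqueness
        if uniq is None:
            uniq = 1.0 - np.diag(R)
        return R + np.diag(uniq)


@dataclass
class FactorScores:
    scores: np.ndarray  # (N, k), columns standardized
    method: str = "regression"


# ---------------------------------------------------------------------------
# extraction


def extract_unrotated(corr: np.ndarray, k: int, max_iter: int = 500) -> np.ndarray:
    """Minimum-residual (ULS) factor extraction.

    Minimises the Frobenius norm of the off-diagonal residuals of
    ``corr - Lambda Lambda'`` over uniquenesses; columns are returned
    ordered by sum of squared loadings, descending, with positive column
    sums.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.shape != (p, p):
        raise ValueError("corr must be square")
    if k >= p:
        raise ValueError("k must be smaller than the number of items")

    def loadings_given_psi(psi: np.ndarray) -> np.ndarray:
        w, V = np.linalg.eigh(corr - np.diag(psi))
        order = np.argsort(w)[::-1][:k]
        lam = np.sqrt(np.clip(w[order], 0.0, None))
        return V[:, order] * lam

    def objective(psi: np.ndarray) -> float:
        L = loadings_given_psi(psi)
        resid = corr - L @ L.T
        np.fill_diagonal(resid, 0.0)
        return float(np.sum(resid**2))

    # start from squared multiple correlations
    try:
        inv = np.linalg.inv(corr)
        smc = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.05, 1.0)
    res = optimize.minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=[(1e-4, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.fun > 1e-6:
        raise RuntimeError(
            f"ULS extraction did not converge: residual norm {res.fun:.3e}"
        )
    L = loadings_given_psi(res.x)
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    L = L[:, order]
    sign = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    return L * sign


# ---------------------------------------------------------------------------
# Geomin criterion


def geomin_criterion(loadings_special: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Geomin value of a p x q loading block (exponent 1/q)."""
    val, _ = _geomin_value_grad(np.asarray(loadings_special, dtype=float), epsilon)
    return val


def _geomin_value_grad(L: np.ndarray, epsilon: float):
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("loading block must be a p x q matrix with q >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    q = L.shape[1]
    L2 = L**2 + epsilon
    # row terms: (prod_r L2_ir)^(1/q), via logs for stability
    logs = np.log(L2)
    row = np.exp(logs.sum(axis=1) / q)
    value = float(row.sum())
    grad = (2.0 / q) * L * (row[:, None] / L2)
    return value, grad


# ---------------------------------------------------------------------------
# gradient-projection rotation


def _project_partial_oblique(T: np.ndarray) -> np.ndarray:
    """Retract onto {unit columns, column 1 orthogonal to the rest}."""
    T = T.copy()
    T[:, 0] /= np.linalg.norm(T[:, 0])
    for r in range(1, T.shape[1]):
        T[:, r] -= (T[:, 0] @ T[:, r]) * T[:, 0]
        nrm = np.linalg.norm(T[:, r])
        if nrm < 1e-12:
            raise RuntimeError("degenerate rotation column during projection")
        T[:, r] /= nrm
    return T


def _project_orthogonal(T: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(T)
    return U @ Vt


def _tangent_project(T: np.ndarray, G: np.ndarray, oblique: bool) -> np.ndarray:
    """Project an ambient gradient onto the tangent space of the manifold."""
    k = T.shape[1]
    if not oblique:
        M = T.T @ G
        return G - T @ (M + M.T) / 2.0
    # constraints: t_r'z_r = 0 for all r; t_1'z_r + t_r'z_1 = 0 for r >= 2
    rows = []
    kk = T.shape[0]
    for r in range(k):
        c = np.zeros((kk, k))
        c[:, r] = T[:, r]
        rows.append(c.ravel())
    for r in range(1, k):
        c = np.zeros((kk, k))
        c[:, r] = T[:, 0]
        c[:, 0] = T[:, r]
        rows.append(c.ravel())
    C = np.array(rows)
    g = G.ravel()
    lam = np.linalg.solve(C @ C.T + 1e-14 * np.eye(len(rows)), C @ g)
    return (g - C.T @ lam).reshape(T.shape)


def _criterion_from_T(A: np.ndarray, T: np.ndarray, epsilon: float, oblique: bool):
    if oblique:
        Tinv = np.linalg.inv(T)
        L = A @ Tinv.T
    else:
        L = A @ T
    val, Gq_special = _geomin_value_grad(L[:, 1:], epsilon)
    Gq = np.zeros_like(L)
    Gq[:, 1:] = Gq_special
    if oblique:
        G = -(L.T @ Gq @ Tinv).T
    else:
        G = A.T @ Gq
    return val, G, L


def _gp_rotate(A: np.ndarray, T0: np.ndarray, epsilon: float, tol: float, oblique: bool):
    """Gradient-projection minimisation of the bifactor Geomin criterion."""
    project = _project_partial_oblique if oblique else _project_orthogonal
    T = project(T0.copy())
    f, G, _ = _criterion_from_T(A, T, epsilon, oblique)
    al = 1.0
    converged = False
    for _ in range(MAX_GP_ITER):
        Gp = _tangent_project(T, G, oblique)
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _ in range(60):
            Tt = project(T - al * Gp)
            ft, Gt, _ = _criterion_from_T(A, Tt, epsilon, oblique)
            if ft < f - 0.5 * s**2 * al * 1e-4:
                T, f, G = Tt, ft, Gt
                improved = True
                break
            al /= 2.0
        if not improved:
            converged = s < 1e2 * tol
            break
    _, _, L = _criterion_from_T(A, T, epsilon, oblique)
    return T, f, L, converged


def _random_start(rng: np.random.Generator, k: int) -> np.ndarray:
    M = rng.standard_normal((k, k))
    Q, _ = np.linalg.qr(M)
    return Q


def bifactor_geomin_rotate(
    unrotated: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    tol: float = ROTATION_TOL,
    oblique: bool = True,
    fix_general: bool = False,
) -> BifactorModel:
    """Rotate an unrotated loading matrix to bifactor Geomin structure.

    Multiple random orthonormal starts (plus the identity) are run through
    gradient projection; the converged solution with the lowest criterion is
    returned (ties within 1e-8 broken by lowest start index).  Sign
    alignment: general factor oriented to positive mean loading, each
    special to a positive largest-magnitude loading.
    """
    A = np.asarray(unrotated, dtype=float)
    p, k = A.shape
    if k < 2:
        raise ValueError("need at least one special factor")
    if fix_general:
        if oblique:
            raise ValueError("fix_general requires the orthogonal rotation")
        return _rotate_specials_only(A, epsilon, n_starts, seed, tol)
    rng = np.random.default_rng(seed)
    starts = [np.eye(k)] + [_random_start(rng, k) for _ in range(max(0, n_starts - 1))]

    best = None
    n_converged = 0
    diagnostics = []
    for idx, T0 in enumerate(starts):
        try:
            T, f, L, ok = _gp_rotate(A, T0, epsilon, tol, oblique)
        except RuntimeError:
            diagnostics.append((idx, np.inf))
            continue
        diagnostics.append((idx, f))
        if ok:
            n_converged += 1
        if ok and (best is None or f < best[1] - 1e-8):
            best = (idx, f, T, L)
    if best is None:
        raise RuntimeError(
            "no rotation start converged; per-start final criteria: "
            + ", ".join(f"{i}:{f:.6g}" for i, f in diagnostics)
        )
    idx, f, T, L = best
    phi = T.T @ T if oblique else np.eye(k)
    # enforce exact structural zeros general<->special
    phi[0, 1:] = 0.0
    phi[1:, 0] = 0.0
    np.fill_diagonal(phi, 1.0)

    L, phi = _align_and_order(L, phi)
    return BifactorModel(
        loadings=L,
        phi=phi,
        criterion_value=f,
        rotation_meta={
            "n_starts": len(starts),
            "converged_starts": n_converged,
            "best_start_index": idx,
            "oblique": oblique,
            "epsilon": epsilon,
        },
    )


def _rotate_specials_only(A, epsilon, n_starts, seed, tol):
    """Orthogonal Geomin rotation of the special columns with the general
    column held fixed — the restricted manifold has exactly the rotational
    freedom among the specials (one angle for two special factors)."""
    p, k = A.shape
    q = k - 1
    rng = np.random.default_rng(seed)
    starts = [np.eye(q)] + [_random_start(rng, q) for _ in range(max(0, n_starts - 1))]
    best = None
    n_conv = 0
    for idx, R0 in enumerate(starts):
        R, f, Ls, ok = _gp_rotate_block(A[:, 1:], R0, epsilon, tol)
        if ok:
            n_conv += 1
        if ok and (best is None or f < best[1] - 1e-8):
            best = (idx, f, R, Ls)
    if best is None:
        raise RuntimeError("no rotation start converged")
    idx, f, R, Ls = best
    L = np.column_stack([A[:, 0], Ls])
    L, phi = _align_and_order(L, np.eye(k))
    return BifactorModel(
        loadings=L, phi=phi, criterion_value=f,
        rotation_meta={"n_starts": len(starts), "converged_starts": n_conv,
                       "best_start_index": idx, "oblique": False,
                       "fix_general": True, "epsilon": epsilon},
    )


def _gp_rotate_block(B, R0, epsilon, tol):
    """Orthogonal gradient projection on a loading block: minimise the
    geomin value of B @ R over rotation matrices R."""
    R = _project_orthogonal(R0.copy())

    def value_grad(R):
        L = B @ R
        val, Gq = _geomin_value_grad(L, epsilon)
        return val, B.T @ Gq, L

    f, G, _ = value_grad(R)
    al = 1.0
    converged = False
    for _ in range(MAX_GP_ITER):
        M = R.T @ G
        Gp = G - R @ (M + M.T) / 2.0
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _ in range(60):
            Rt = _project_orthogonal(R - al * Gp)
            ft, Gt, _ = value_grad(Rt)
            if ft < f - 0.5 * s**2 * al * 1e-4:
                R, f, G = Rt, ft, Gt
                improved = True
                break
            al /= 2.0
        if not improved:
            converged = s < 1e2 * tol
            break
    _, _, L = value_grad(R)
    return R, f, L, converged


def _align_and_order(L: np.ndarray, phi: np.ndarray):
    """Column 1 = general; specials ordered by SS loadings; signs aligned."""
    L = L.copy()
    phi = phi.copy()
    k = L.shape[1]
    # general column: the one with the largest minimum |loading| across items
    # (all items load on the general factor)
    general = int(np.argmax(np.min(np.abs(L), axis=0)))
    order = [general] + sorted(
        (r for r in range(k) if r != general),
        key=lambda r: -np.sum(L[:, r] ** 2),
    )
    L = L[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.ones(k)
    if L[:, 0].mean() < 0:
        signs[0] = -1.0
    for r in range(1, k):
        if L[np.argmax(np.abs(L[:, r])), r] < 0:
            signs[r] = -1.0
    L = L * signs
    phi = phi * np.outer(signs, signs)
    np.fill_diagonal(phi, 1.0)
    return L, phi


# ---------------------------------------------------------------------------
# fit indices


def fit_indices(corr: np.ndarray, model: BifactorModel, n: int) -> dict:
    """RMSEA, CFI, TLI and SRMR from the ULS discrepancy.

    The ULS discrepancy F = sum of squared non-redundant residuals / 2 is
    converted to a chi-square-scale statistic T = (n - 1) F; degrees of
    freedom follow the standard EFA bookkeeping df = ((p-k)^2 - (p+k)) / 2;
    the baseline is the independence model with df0 = p(p-1)/2.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    k = model.k
    df = ((p - k) ** 2 - (p + k)) / 2.0
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df}) for p={p}, k={k}")
    implied = model.implied_corr()
    resid = corr - implied
    off = resid[np.triu_indices(p, 1)]
    F = float(np.sum(off**2))
    diag0 = corr[np.triu_indices(p, 1)]
    F0 = float(np.sum(diag0**2))
    df0 = p * (p - 1) / 2.0
    T = (n - 1) * F
    T0 = (n - 1) * F0
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
    denom = max(T - df, T0 - df0, 0.0)
    cfi = 1.0 if denom == 0 else float(1.0 - max(T - df, 0.0) / denom)
    if T0 / df0 - 1.0 <= 0:
        tli = 1.0
    else:
        tli = float((T0 / df0 - T / df) / (T0 / df0 - 1.0))
        if T <= df:
            tli = min(tli, 1.0) if F == 0 else tli
    # SRMR over the p(p+1)/2 non-redundant elements (diagonal residuals 0)
    srmr = float(np.sqrt((np.sum(off**2) + 0.0) / (p * (p + 1) / 2.0)))
    return {"rmsea": rmsea, "cfi": cfi, "tli": tli, "srmr": srmr}


# ---------------------------------------------------------------------------
# factor scores


def factor_scores(responses, model: BifactorModel) -> FactorScores:
    """Regression-method (Thurstone) factor scores on the liability scale.

    Binary items are represented by their standardized indicators; weights
    are Phi Lambda' (Lambda Phi Lambda' + diag(uniqueness))^-1 from the
    fitted measurement model.  Score columns are standardized before use.
    """
    X = np.asarray(getattr(responses, "responses", responses), dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    implied = model.implied_corr()
    try:
        W = model.phi @ model.loadings.T @ np.linalg.inv(implied)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("model-implied correlation matrix is singular") from exc
    S = X @ W.T
    S = (S - S.mean(axis=0)) / S.std(axis=0)
    return FactorScores(scores=S, method="regression")


# ---------------------------------------------------------------------------
# congruence


def congruence(loadings_a: np.ndarray, loadings_b: np.ndarray):
    """Tucker congruence coefficients of two loading matrices.

    Columns are matched by maximizing total |congruence| over permutations,
    with sign freedom; returns ``(coefficients, permutation, sign_flips)``
    where ``coefficients[j]`` compares column j of A with column
    ``permutation[j]`` of B after flipping signs ``sign_flips[j]``.
    """
    A = np.asarray(loadings_a, dtype=float)
    B = np.asarray(loadings_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("loading matrices must have equal shapes")
    k = A.shape[1]
    na = np.sqrt(np.sum(A**2, axis=0))
    nb = np.sqrt(np.sum(B**2, axis=0))
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero loading column: congruence undefined")
    C = (A.T @ B) / np.outer(na, nb)
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(k)):
        total = sum(abs(C[j, perm[j]]) for j in range(k))
        if total > best_total:
            best_total, best_perm = total, perm
    coeffs = np.array([C[j, best_perm[j]] for j in range(k)])
    signs = np.where(coeffs < 0, -1.0, 1.0)
    return coeffs * signs, tuple(best_perm), signs


# ---------------------------------------------------------------------------
# one-call fit


def fit_bifactor(
    polychoric,
    n: int,
    k: int = 3,
    epsilon: float = DEFAULT_EPSILON,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    oblique: bool = True,
) -> BifactorModel:
    """Extract + rotate + fit indices from a PolychoricResult (or matrix)."""
    corr = getattr(polychoric, "corr_psd", polychoric)
    thresholds = getattr(polychoric, "thresholds", None)
    A = extract_unrotated(corr, k)
    model = bifactor_geomin_rotate(
        A, epsilon=epsilon, n_starts=n_starts, seed=seed, oblique=oblique
    )
    model.thresholds = thresholds
    implied_common = model.loadings @ model.phi @ model.loadings.T
    model.uniqueness = 1.0 - np.diag(implied_common)
    raw = getattr(polychoric, "corr", corr)
    model.fit = fit_indices(np.asarray(raw, dtype=float), model, n)
    model.variance_explained = np.sum(model.loadings**2, axis=0) / corr.shape[0]
    return model
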