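"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most direct route available
(enumeration, quadrature, dense search) and stay independent of the library
code paths they check.
"""

import itertools

import numpy as np
from scipy import integrate, stats


# ---------------------------------------------------------------------------
# thresholded bivariate normal (genotype LD oracle)


def thresholded_pair_correlation(rho: float, p_a: float, p_b: float) -> float:
    """Correlation of two Bernoulli variables obtained by thresholding a
    standard bivariate normal with correlation rho at the upper-tail cuts
    for frequencies p_a, p_b, via 2-D Gaussian quadrature.

    The correlation of dosages (sums of two iid thresholded haplotypes)
    equals the correlation of a single thresholded pair.
    """
    ta, tb = stats.norm.ppf(1 - p_a), stats.norm.ppf(1 - p_b)

    def dens(y, x):
        det = 1 - rho**2
        return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det)) / (
            2 * np.pi * np.sqrt(det)
        )

    p11, _ = integrate.dblquad(dens, ta, 8.0, lambda x: tb, lambda x: 8.0,
                               epsabs=1e-10)
    cov = p11 - p_a * p_b
    return cov / np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))


# ---------------------------------------------------------------------------
# tetrachoric: invert the orthant probability numerically


def tetrachoric_from_table(n00, n01, n10, n11) -> float:
    """Grid + bisection inversion of the bivariate-normal orthant probability
    at thresholds fixed from the margins."""
    n = n00 + n01 + n10 + n11
    ta = stats.norm.ppf((n00 + n01) / n)
    tb = stats.norm.ppf((n00 + n10) / n)
    target = n11 / n

    def p11(rho):
        def dens(y, x):
            det = 1 - rho**2
            return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det)) / (
                2 * np.pi * np.sqrt(det)
            )

        val, _ = integrate.dblquad(dens, ta, 8.0, lambda x: tb, lambda x: 8.0,
                                   epsabs=1e-10)
        return val

    lo, hi = -0.999, 0.999
    for _ in range(60):
        mid = (lo + hi) / 2
        if p11(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# geomin by brute force over a single special-column rotation angle


def geomin_angle_grid(A: np.ndarray, epsilon: float, resolution: float = 1e-4):
    """Minimum over theta of the geomin value of the two special columns of
    A rotated by R(theta), at the given grid resolution."""
    thetas = np.arange(0.0, np.pi / 2, resolution)  # geomin has period pi/2 up to sign
    best = np.inf
    for th in thetas:
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, -s], [s, c]])
        L = A[:, 1:] @ R
        val = np.sum(np.sqrt((L[:, 0] ** 2 + epsilon) * (L[:, 1] ** 2 + epsilon)))
        if val < best:
            best = val
    return best


# ---------------------------------------------------------------------------
# BH step-up by definition


def bh_reject_bruteforce(pvals, q):
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_max = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


# ---------------------------------------------------------------------------
# four-step locus definition by direct enumeration


def define_loci_bruteforce(table, r2_lookup, p_gw=5e-8, r2_indep=0.6,
                           r2_lead=0.1, window_kb=1000.0, merge_kb=250.0):
    """Plain-python enumeration of the four locus-definition steps.

    ``table``: records with SNP/CHR/BP/P; ``r2_lookup(a, b)`` -> r^2.
    Returns a list of dicts {chrom, start, end, leads, indep, members}.
    """
    recs = [
        {"snp": s, "chrom": int(c), "bp": int(b), "p": float(p)}
        for s, c, b, p in zip(table["SNP"], table["CHR"], table["BP"], table["P"])
    ]
    win = window_kb * 1000.0

    def near(a, b):
        return a["chrom"] == b["chrom"] and abs(a["bp"] - b["bp"]) <= win

    sig = [r for r in recs if r["p"] < p_gw]
    sig.sort(key=lambda r: (r["p"], r["chrom"], r["bp"]))

    # step 1
    indep = []
    for cand in sig:
        if all(not near(cand, kept) or r2_lookup(cand["snp"], kept["snp"]) < r2_indep
               for kept in indep):
            indep.append(cand)

    # step 2
    members = {}
    for i in indep:
        members[i["snp"]] = [
            r["snp"] for r in recs
            if near(i, r) and (r is i or r2_lookup(i["snp"], r["snp"]) >= r2_indep)
        ]

    # step 3
    leads = []
    for cand in indep:
        if all(not near(cand, kept) or r2_lookup(cand["snp"], kept["snp"]) < r2_lead
               for kept in leads):
            leads.append(cand)

    # step 4: single-linkage clusters of leads closer than merge_kb
    leads_sorted = sorted(leads, key=lambda r: (r["chrom"], r["bp"]))
    clusters = []
    for lead in leads_sorted:
        if clusters and clusters[-1][-1]["chrom"] == lead["chrom"] \
                and lead["bp"] - clusters[-1][-1]["bp"] < merge_kb * 1000.0:
            clusters[-1].append(lead)
        else:
            clusters.append([lead])

    # independent SNPs attach to the cluster of the best-p lead they tag
    lead_snps = {l["snp"] for l in leads}
    loci = []
    for cluster in clusters:
        cset = {l["snp"] for l in cluster}
        my_indep = []
        for i in indep:
            if i["snp"] in cset:
                my_indep.append(i)
                continue
            if i["snp"] in lead_snps:
                continue
            linked = [l for l in leads
                      if near(i, l) and r2_lookup(i["snp"], l["snp"]) >= r2_lead]
            if linked:
                best = min(linked, key=lambda l: (l["p"], l["chrom"], l["bp"]))
                if best["snp"] in cset:
                    my_indep.append(i)
        mem = sorted({m for i in my_indep for m in members[i["snp"]]})
        bp_of = {r["snp"]: r["bp"] for r in recs}
        positions = [bp_of[s] for s in mem]
        loci.append({
            "chrom": cluster[0]["chrom"],
            "start": min(positions),
            "end": max(positions),
            "leads": sorted(cset),
            "indep": sorted(i["snp"] for i in my_indep),
            "members": mem,
        })
    # merge any overlapping intervals on the same chromosome
    loci.sort(key=lambda l: (l["chrom"], l["start"]))
    merged = []
    for loc in loci:
        if merged and merged[-1]["chrom"] == loc["chrom"] \
                and loc["start"] <= merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], loc["end"])
            prev["leads"] = sorted(set(prev["leads"]) | set(loc["leads"]))
            prev["indep"] = sorted(set(prev["indep"]) | set(loc["indep"]))
            prev["members"] = sorted(set(prev["members"]) | set(loc["members"]))
        else:
            merged.append(loc)
    return merged


def overlap_count_quadratic(loci_a, loci_b):
    count = 0
    for la in loci_a:
        if any(
            la.chrom == lb.chrom
            and la.start_bp <= lb.end_bp
            and lb.start_bp <= la.end_bp
            for lb in loci_b
        ):
            count += 1
    return count


# ---------------------------------------------------------------------------
# generic OLS oracle


def ols_oracle(X, y):
    """Slope/SE/residuals of y on [1, X] via the normal equations."""
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(XtX)
    return coef, np.sqrt(np.diag(cov)), resid


def permutations_congruence(A, B):
    """Best total |cosine| over column permutations, by full enumeration."""
    k = A.shape[1]
    best = -np.inf
    for perm in itertools.permutations(range(k)):
        tot = 0.0
        for j in range(k):
            a, b = A[:, j], B[:, perm[j]]
            tot += abs(a @ b / np.sqrt((a @ a) * (b @ b)))
        best = max(best, tot)
    return best
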