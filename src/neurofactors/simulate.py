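"""Seeded synthetic cohorts: LD-blocked genotypes, correlated latent factors,
and binary questionnaire items from a threshold (liability) bifactor model.

The generator emulates the cohort design this package analyses: a 12-item
yes/no neuroticism questionnaire measuring one general factor plus an
anxiety/tension special factor (3 salient items) and a worry/vulnerability
special factor (4 salient items), with per-factor SNP heritabilities and
between-factor genetic correlations imposed on genotypes laid out in AR(1)
LD blocks across 22 autosomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "LatentFactorTable",
    "ItemResponseMatrix",
    "ConfigError",
    "EPQN_ITEM_LABELS",
    "DEFAULT_LOADINGS",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_H2",
    "DEFAULT_RG",
    "PHI_SPECIAL",
    "simulate_genotypes",
    "simulate_factors",
    "simulate_items",
    "simulate_cohort",
    "draw_architecture",
    "GeneticArchitecture",
]

N_AUTOSOMES = 22
BP_SPACING = 10_000  # base pairs between adjacent SNPs on a chromosome

#: The 12 yes/no items of the short-scale EPQ-R neuroticism scale.
EPQN_ITEM_LABELS = (
    "mood_swings",            # Does your mood often go up and down?
    "miserableness",          # Do you ever feel 'just miserable' for no reason?
    "irritability",           # Are you an irritable person?
    "sensitivity",            # Are your feelings easily hurt?
    "fed_up",                 # Do you often feel 'fed-up'?
    "nervous",                # Would you call yourself a nervous person?
    "worrier",                # Are you a worrier?
    "tense",                  # Would you call yourself tense or 'highly strung'?
    "embarrassment_worry",    # Do you worry too long after an embarrassing experience?
    "nerves",                 # Do you suffer from 'nerves'?
    "loneliness",             # Do you often feel lonely?
    "guilt",                  # Are you often troubled by feelings of guilt?
)

# Columns: general factor (all 12 items), anxiety/tension (nervous, tense,
# nerves), worry/vulnerability (sensitivity, worrier, embarrassment_worry,
# guilt).  Special-factor salient loadings use the reported item loadings
# (0.60/0.49/0.35 and 0.57/0.40/0.31/0.31); general loadings are chosen so
# the general factor explains ~29% of total item variance.
DEFAULT_LOADINGS = np.array(
    [
        # general  anx/ten  worry/vuln
        [0.66, 0.00, 0.00],  # mood_swings
        [0.61, 0.00, 0.00],  # miserableness
        [0.48, 0.00, 0.00],  # irritability
        [0.56, 0.00, 0.40],  # sensitivity
        [0.65, 0.00, 0.00],  # fed_up
        [0.51, 0.60, 0.00],  # nervous
        [0.63, 0.00, 0.31],  # worrier
        [0.52, 0.35, 0.00],  # tense
        [0.50, 0.00, 0.57],  # embarrassment_worry
        [0.55, 0.49, 0.00],  # nerves
        [0.49, 0.00, 0.00],  # loneliness
        [0.52, 0.00, 0.31],  # guilt
    ]
)

# Standard-normal thresholds on the item liabilities; endorsement rate of
# item i is Phi(-threshold_i), spanning roughly 25-60% across items.
DEFAULT_THRESHOLDS = np.array(
    [-0.25, 0.10, 0.30, -0.10, -0.20, 0.55, -0.30, 0.45, 0.05, 0.60, 0.40, 0.20]
)

#: SNP heritabilities of (general, anxiety/tension, worry/vulnerability).
DEFAULT_H2 = (0.107, 0.057, 0.064)

#: Genetic correlations among the three factors.
DEFAULT_RG = np.array(
    [
        [1.00, 0.20, 0.35],
        [0.20, 1.00, 0.66],
        [0.35, 0.66, 1.00],
    ]
)

#: Model correlation of the two special factors.
PHI_SPECIAL = 0.311


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def _default_rg() -> np.ndarray:
    return DEFAULT_RG.copy()


def _default_loadings() -> np.ndarray:
    return DEFAULT_LOADINGS.copy()


def _default_thresholds() -> np.ndarray:
    return DEFAULT_THRESHOLDS.copy()


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    ``h2`` and ``rg_matrix`` may describe more than three traits: the first
    three are always the (general, anxiety/tension, worry/vulnerability)
    factors measured by the questionnaire; any further entries are auxiliary
    quantitative traits (e.g. an income-like outcome) whose environmental
    residuals are independent of the factors, so their phenotypic
    correlation with each factor equals the genetic covariance.
    """

    n_individuals: int = 20_000
    n_snps: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 50
    ld_rho: float = 0.8
    # heterogeneous LD: per-block AR(1) coefficient drawn uniformly from this
    # range (None = use the single ld_rho everywhere).  Real LD scores vary by
    # orders of magnitude across the genome; LD-score regression needs that
    # variation to identify the slope.
    ld_rho_range: tuple[float, float] | None = (0.1, 0.98)
    h2: tuple[float, ...] = DEFAULT_H2
    rg_matrix: np.ndarray = field(default_factory=_default_rg)
    phi_special: float = PHI_SPECIAL
    loading_matrix: np.ndarray = field(default_factory=_default_loadings)
    item_thresholds: np.ndarray = field(default_factory=_default_thresholds)
    # dense polygenic architecture: neuroticism-like traits are highly
    # polygenic, and LD-score regression itself assumes the per-SNP signal
    # tracks the LD score, which a sparse causal set realises only noisily
    n_causal_frac: float = 1.0
    covariate_betas: np.ndarray | None = None  # (2, K): rows = (age, sex)
    seed: int = 0

    def __post_init__(self) -> None:
        self.rg_matrix = np.asarray(self.rg_matrix, dtype=float)
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        self.item_thresholds = np.asarray(self.item_thresholds, dtype=float)
        self.validate()

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be at least 2")
        if self.n_snps < 1 or self.ld_block_size < 1:
            raise ConfigError("n_snps and ld_block_size must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.ld_rho_range is not None:
            rlo, rhi = self.ld_rho_range
            if not (0.0 <= rlo <= rhi < 1.0):
                raise ConfigError(
                    f"ld_rho_range must lie in [0, 1), got {self.ld_rho_range}"
                )
        if not (0.0 < self.n_causal_frac <= 1.0):
            raise ConfigError("n_causal_frac must lie in (0, 1]")
        h2 = np.asarray(self.h2, dtype=float)
        if np.any(h2 < 0) or np.any(h2 > 1):
            raise ConfigError(f"all h2 must lie in [0, 1], got {tuple(h2)}")
        K = len(h2)
        if K < 3:
            raise ConfigError("h2 must cover at least the three factors")
        G = self.rg_matrix
        if G.shape != (K, K):
            raise ConfigError(f"rg_matrix must be {K}x{K}, got {G.shape}")
        if not np.allclose(G, G.T, atol=1e-12):
            raise ConfigError("rg_matrix must be symmetric")
        if not np.allclose(np.diag(G), 1.0, atol=1e-12):
            raise ConfigError("rg_matrix must have unit diagonal")
        if np.linalg.eigvalsh(G).min() < -1e-8:
            raise ConfigError("rg_matrix must be positive semi-definite")
        if not (-1.0 <= self.phi_special <= 1.0):
            raise ConfigError("phi_special must lie in [-1, 1]")
        L = self.loading_matrix
        if L.shape != (12, 3):
            raise ConfigError(f"loading_matrix must be 12x3, got {L.shape}")
        phi = factor_phi(self.phi_special)
        communality = np.einsum("ir,rs,is->i", L, phi, L)
        if np.any(communality > 1.0 + 1e-12):
            bad = np.nonzero(communality > 1.0 + 1e-12)[0]
            raise ConfigError(
                f"item communalities exceed 1 for item rows {bad.tolist()}"
            )
        if self.item_thresholds.shape != (12,):
            raise ConfigError("item_thresholds must have length 12")


def factor_phi(phi_special: float) -> np.ndarray:
    """3x3 factor correlation matrix: general orthogonal to both specials."""
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, phi_special],
            [0.0, phi_special, 1.0],
        ]
    )


@dataclass
class GenotypeMatrix:
    """Hard-call dosages in {0,1,2} with a synthetic genomic layout."""

    dosages: np.ndarray  # (N, M) int8
    snp_ids: np.ndarray  # (M,) str
    chrom: np.ndarray    # (M,) int
    bp: np.ndarray       # (M,) int, 1-based
    a1: np.ndarray       # (M,) effect allele
    a2: np.ndarray       # (M,) other allele
    maf: np.ndarray      # (M,) empirical minor allele frequency

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def freq_a1(self) -> np.ndarray:
        """Empirical a1 allele frequency per SNP."""
        return self.dosages.mean(axis=0) / 2.0

    def standardized(self, dtype=np.float32) -> np.ndarray:
        """Column-standardized dosage matrix (mean 0, variance 1 per SNP)."""
        X = self.dosages.astype(dtype)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic SNP cannot be standardized")
        X /= sd
        return X

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            bp=self.bp[mask],
            a1=self.a1[mask],
            a2=self.a2[mask],
            maf=self.maf[mask],
        )


@dataclass
class GeneticArchitecture:
    """Shared causal-SNP set and per-SNP effects of a simulated population.

    Drawing the architecture once and reusing it across cohorts makes the
    cohorts samples from one population — the situation a polygenic-score
    replication design assumes.
    """

    causal_idx: np.ndarray   # indices into the SNP panel
    betas: np.ndarray        # (n_causal, K) unscaled per-standardized-SNP effects


@dataclass
class LatentFactorTable:
    """True latent traits: phenotype = genetic value + environment."""

    scores_true: np.ndarray      # (N, K) standardized phenotypic values
    genetic_values: np.ndarray   # (N, K) additive genetic components
    covariates: "object"         # pandas.DataFrame with age, sex
    causal_idx: np.ndarray       # indices of causal SNPs
    causal_betas: np.ndarray     # (n_causal, K) per-standardized-SNP effects


@dataclass
class ItemResponseMatrix:
    """N x 12 binary questionnaire answers (1 = yes, 0 = no)."""

    responses: np.ndarray  # (N, 12) int8
    item_labels: tuple[str, ...] = EPQN_ITEM_LABELS

    @property
    def n_individuals(self) -> int:
        return self.responses.shape[0]


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw dosages by thresholding latent AR(1) Gaussians within LD blocks.

    Two independent haplotypes per individual are thresholded and summed;
    blocks are internally AR(1)-correlated with coefficient ``ld_rho`` and
    independent of each other, and are assigned round-robin to the 22
    autosomes with positions spaced 10 kb apart.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, M, B = config.n_individuals, config.n_snps, config.ld_block_size
    lo, hi = config.maf_range

    target_maf = rng.uniform(lo, hi, size=M)
    # allele = 1 when latent exceeds the upper-tail cut for frequency p
    cuts = stats.norm.ppf(1.0 - target_maf).astype(np.float32)

    dosages = np.empty((n, M), dtype=np.int8)
    n_blocks = (M + B - 1) // B
    if config.ld_rho_range is None:
        block_rho = np.full(n_blocks, config.ld_rho, dtype=np.float32)
    else:
        rlo, rhi = config.ld_rho_range
        block_rho = rng.uniform(rlo, rhi, size=n_blocks).astype(np.float32)
    # process groups of blocks together; layout (within-block SNP, block,
    # haplotype*individual) keeps the AR(1) recursion on contiguous slabs
    group = max(1, 25_000_000 // max(1, 2 * n * B))
    b0 = 0
    while b0 < n_blocks:
        b1 = min(b0 + group, n_blocks)
        g = b1 - b0
        j0 = b0 * B
        j1 = min(b1 * B, M)
        width_last = j1 - (b1 - 1) * B  # < B only for the final ragged block
        eps = rng.standard_normal((B, g, 2 * n), dtype=np.float32)
        rho = block_rho[b0:b1][:, None]
        innov = np.sqrt(1.0 - rho**2)
        for j in range(1, B):
            eps[j] *= innov
            eps[j] += rho * eps[j - 1]
        # to (block, within-block SNP, 2n) then flatten the SNP axis
        lat = np.ascontiguousarray(eps.transpose(1, 0, 2)).reshape(g * B, 2 * n)
        lat = lat[: j1 - j0] if width_last == B else np.vstack(
            [lat[: (g - 1) * B], lat[(g - 1) * B : (g - 1) * B + width_last]]
        )
        alleles = lat > cuts[j0:j1, None]
        dosages[:, j0:j1] = (
            alleles[:, :n].astype(np.int8) + alleles[:, n:].astype(np.int8)
        ).T
        b0 = b1

    # redraw any monomorphic column so empirical MAF > 0
    for j in np.nonzero(np.ptp(dosages, axis=0) == 0)[0]:
        for _ in range(1000):
            hap = rng.standard_normal((2, n), dtype=np.float32) > cuts[j]
            col = hap[0].astype(np.int8) + hap[1].astype(np.int8)
            if np.ptp(col) > 0:
                dosages[:, j] = col
                break
        else:  # pragma: no cover - requires pathological maf_range
            raise RuntimeError(f"could not generate a polymorphic SNP at index {j}")

    block_of = np.arange(M) // B
    chrom = (block_of % N_AUTOSOMES + 1).astype(np.int32)
    bp = np.empty(M, dtype=np.int64)
    for c in range(1, N_AUTOSOMES + 1):
        idx = np.nonzero(chrom == c)[0]
        bp[idx] = BP_SPACING * (np.arange(len(idx)) + 1)
    snp_ids = np.array([f"rs{j + 1}" for j in range(M)])
    freq = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=chrom,
        bp=bp,
        a1=np.full(M, "A"),
        a2=np.full(M, "G"),
        maf=np.minimum(freq, 1.0 - freq),
    )


# ---------------------------------------------------------------------------
# latent factors


def _target_phenotypic_corr(config: SimulationConfig) -> np.ndarray:
    """Total-trait correlation targets.

    The three factors correlate (0, 0, phi_special); auxiliary traits get
    independent environments, so their phenotypic correlation with every
    other trait equals the genetic covariance.
    """
    K = config.n_traits
    h = np.sqrt(np.asarray(config.h2, dtype=float))
    gcov = config.rg_matrix * np.outer(h, h)
    P = gcov.copy()
    np.fill_diagonal(P, 1.0)
    P[:3, :3] = factor_phi(config.phi_special)
    return P


def draw_architecture(config: SimulationConfig, n_snps: int | None = None) -> GeneticArchitecture:
    """Draw the shared causal set and correlated per-SNP effects.

    Seeded by ``config.seed`` alone, so two cohorts built from configs that
    differ only in cohort-level fields can share one architecture.
    """
    config.validate()
    K = config.n_traits
    M = config.n_snps if n_snps is None else n_snps
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    m_causal = max(1, int(round(config.n_causal_frac * M)))
    causal_idx = np.sort(rng.choice(M, size=m_causal, replace=False))
    chol_g = np.linalg.cholesky(config.rg_matrix + 1e-12 * np.eye(K))
    betas = rng.standard_normal((m_causal, K)) @ chol_g.T
    betas *= np.sqrt(np.asarray(config.h2, dtype=float) / m_causal)
    return GeneticArchitecture(causal_idx=causal_idx, betas=betas)


def simulate_factors(
    genotypes: GenotypeMatrix | None,
    config: SimulationConfig,
    architecture: GeneticArchitecture | None = None,
) -> LatentFactorTable:
    """Build latent traits with the configured genetic architecture.

    Causal effects are drawn for a shared causal-SNP set from a K-variate
    normal with correlation ``rg_matrix``; each genetic value is the
    standardized-genotype score rescaled to variance ``h2``; environmental
    residuals complete the target phenotypic correlations; traits are
    standardized to unit variance.

    ``genotypes`` may be None only when every h2 is zero (pure measurement
    simulations).
    """
    config.validate()
    K = config.n_traits
    h2 = np.asarray(config.h2, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    if genotypes is None:
        if np.any(h2 > 0):
            raise ConfigError("genotypes are required when any h2 > 0")
        n = config.n_individuals
    else:
        n = genotypes.n_individuals

    gcov = config.rg_matrix * np.outer(np.sqrt(h2), np.sqrt(h2))
    P = _target_phenotypic_corr(config)
    ecov = P - gcov
    evals = np.linalg.eigvalsh(ecov)
    if evals.min() < -1e-10:
        bad = [
            (i, j)
            for i, j in itertools.combinations(range(K), 2)
            if abs(ecov[i, j]) > 1.0 - h2[[i, j]].max()
        ]
        raise ConfigError(
            "environmental covariance implied by h2/rg/phi_special is not "
            f"positive semi-definite (min eigenvalue {evals.min():.3g}); "
            f"check trait pairs {bad or 'on the diagonal'}"
        )

    genetic = np.zeros((n, K))
    if genotypes is not None and np.any(h2 > 0):
        if architecture is None:
            architecture = draw_architecture(config, n_snps=genotypes.n_snps)
        causal_idx = architecture.causal_idx
        betas = architecture.betas.copy()
        Xc = genotypes.dosages[:, causal_idx].astype(np.float32)
        Xc -= Xc.mean(axis=0)
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc /= sd
        genetic = (Xc @ betas.astype(np.float32)).astype(float)
        # rescale each genetic value to variance exactly h2
        gsd = genetic.std(axis=0)
        for k in range(K):
            if h2[k] > 0 and gsd[k] > 0:
                scale = np.sqrt(h2[k]) / gsd[k]
                genetic[:, k] *= scale
                betas[:, k] *= scale
    else:
        causal_idx = np.empty(0, dtype=int)
        betas = np.empty((0, K))

    # eigenvalue-clipped square root handles PSD-boundary configurations
    w, V = np.linalg.eigh(ecov)
    sqrt_e = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    env = rng.standard_normal((n, K)) @ sqrt_e.T
    scores = genetic + env
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)

    covariates = _simulate_covariates(n, rng)
    if config.covariate_betas is not None:
        cb = np.asarray(config.covariate_betas, dtype=float)
        design = np.column_stack(
            [
                (covariates["age"].to_numpy() - 56.0) / 10.0,
                covariates["sex"].to_numpy(),
            ]
        )
        scores = scores + design @ cb
    return LatentFactorTable(
        scores_true=scores,
        genetic_values=genetic,
        covariates=covariates,
        causal_idx=causal_idx,
        causal_betas=betas,
    )


def _simulate_covariates(n: int, rng: np.random.Generator):
    import pandas as pd

    return pd.DataFrame(
        {
            "age": rng.uniform(39.0, 73.0, size=n),
            "sex": rng.integers(0, 2, size=n),
        }
    )


# ---------------------------------------------------------------------------
# items


def simulate_items(
    factors: LatentFactorTable, config: SimulationConfig
) -> ItemResponseMatrix:
    """Threshold the bifactor liabilities into 12 binary responses.

    Item liability is y* = Lambda f + e with e normal and scaled so the
    liability has unit variance under the model-implied correlation
    Lambda Phi Lambda' + diag(uniqueness); the response is 1 iff y* exceeds
    the item threshold.
    """
    config.validate()
    L = config.loading_matrix
    phi = factor_phi(config.phi_special)
    uniq = 1.0 - np.einsum("ir,rs,is->i", L, phi, L)
    if np.any(uniq < -1e-12):
        raise ConfigError("item communality exceeds 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    f = factors.scores_true[:, :3]
    liability = f @ L.T
    liability += rng.standard_normal(liability.shape) * np.sqrt(np.clip(uniq, 0, None))
    responses = (liability > config.item_thresholds).astype(np.int8)
    return ItemResponseMatrix(responses=responses)


def latent_item_correlation(config: SimulationConfig) -> np.ndarray:
    """Analytic correlation of the item liabilities: Lambda Phi Lambda' + diag."""
    L = config.loading_matrix
    phi = factor_phi(config.phi_special)
    R = L @ phi @ L.T
    np.fill_diagonal(R, 1.0)
    return R


def simulate_cohort(
    config: SimulationConfig, architecture: GeneticArchitecture | None = None
):
    """Convenience wrapper: genotypes + factors + items for one cohort."""
    genotypes = simulate_genotypes(config)
    factors = simulate_factors(genotypes, config, architecture=architecture)
    items = simulate_items(factors, config)
    return genotypes, factors, items
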