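# Methods

This package implements, end to end on synthetic cohorts, the analysis
pipeline that decomposes a 12-item yes/no neuroticism questionnaire into a
general factor and two special factors (anxiety/tension; worry/vulnerability)
and then contrasts the three factors' genetic architectures: per-factor
GWAS, LD-score-regression heritability and genetic correlation, genomic
risk-locus definition, and polygenic-score prediction into a second cohort.

## The measurement model

Item i's liability is

    y*_i = lambda_i1 f_g + lambda_i2 f_a + lambda_i3 f_w + e_i,
    response_i = 1  iff  y*_i > tau_i,

with factors standardized, Phi[g,a] = Phi[g,w] = 0 by model constraint,
Phi[a,w] = 0.311 by default, and unique variance
1 − lambda_i' Phi lambda_i, so the liabilities have unit variance and latent
correlation Lambda Phi Lambda' + diag(uniqueness).  The default loading
matrix puts the general factor on all 12 items (explaining ≈ 29–31% of item
variance), the anxiety/tension factor on three items (loadings 0.60, 0.49,
0.35) and the worry/vulnerability factor on four (0.57, 0.40, 0.31, 0.31);
thresholds give endorsement rates of roughly 25–60%.

### Tetrachoric correlations

Two-step maximum likelihood: thresholds fixed at the inverse-normal of the
item margins; the latent correlation of each pair maximizes the multinomial
likelihood of the 2×2 table over the bivariate-normal orthant
probabilities.  The bivariate normal CDF is evaluated by the single-integral
reduction (integrating the density over the correlation parameter) with
adaptive quadrature at absolute tolerance 1e−10; the 1-D likelihood search
uses tolerance 1e−8 and caps |rho| at 0.999.  An empty contingency cell
returns the boundary estimate with a flag instead of raising.  If the
pairwise matrix is not positive semi-definite, an eigenvalue-clipped copy
(floor 1e−8, rescaled to unit diagonal) is stored alongside the raw matrix
and used for extraction.

### Extraction and rotation

Factors are extracted by minimum-residual (ULS) factoring: uniquenesses are
optimized (L-BFGS-B) to minimize the sum of squared off-diagonal residuals,
with loadings from the eigendecomposition of the reduced matrix.  This is a
desk-scale stand-in for the WLSMV estimator of commercial SEM software; the
difference is far below the tolerances used in the tests.

Rotation minimizes the Geomin criterion

    sum_i ( prod_{r in specials} (lambda_ir^2 + eps) )^(1/q),  q = k − 1,

applied to the special columns only, by gradient projection on a partially
oblique manifold: rotation-matrix columns have unit norm, the general
column is orthogonal to the special columns (the model's zero-correlation
constraint enforced during rotation, not after), and the specials are free
to correlate.  Thirty seed-controlled orthonormal starts are run (identity
first); the lowest converged criterion wins, ties within 1e−8 going to the
lowest start index.  Signs are aligned so the general factor's mean loading
and each special factor's largest-magnitude loading are positive.

**Epsilon and factor collapse.**  The criterion is conventionally quoted
with eps = 0.01.  For *fitting* we default to eps = 1e−4, for a reason that
can be demonstrated exactly: on the noise-free population matrix
Lambda Phi Lambda' + diag of the default generative model, the global
optimum of the bifactor Geomin criterion at eps = 0.01 is not the
generative structure but a partially collapsed solution in which the
general factor absorbs part of the special-factor correlation (maximum
loading displacement 0.108; special-factor correlation 0.08 instead of
0.311).  This is the documented collapse tendency of bifactor Geomin
rotations: a large eps dilutes the reward for exact zeros, and the
criterion — which never sees the general column — prefers shrinking the
(correlated) specials into it.  At eps = 1e−4 the optimum coincides with
the generative structure (maximum displacement 0.006).  Mainstream software
likewise uses small, factor-count-dependent epsilons internally.  The
criterion function itself accepts any eps, and the rotation oracle test
evaluates it at 0.01.

A restricted mode (`fix_general=True`, orthogonal) holds the general column
fixed and rotates the specials only; with two special factors this manifold
has exactly one rotational degree of freedom, which makes a brute-force
angle-grid oracle possible.  The unrestricted rotation can only attain an
equal or lower criterion, which the tests also assert.

### Fit indices and factor scores

The ULS discrepancy F (sum of squared non-redundant residuals) is converted
to T = (n−1)F with EFA degrees of freedom df = ((p−k)² − (p+k))/2 and
independence baseline df0 = p(p−1)/2; RMSEA, CFI, TLI and SRMR follow the
standard formulas.  T is not chi-square distributed under ULS, so the
indices are comparative descriptives, not test statistics — the use the
pipeline makes of them.

Factor scores use the regression (Thurstone) method on the liability scale
with standardized binary indicators: W = Phi Lambda' Sigma^{-1} with
Sigma the model-implied correlation matrix; columns standardized.
Categorical MAP scoring is not reproduced; the known consequence — score
correlations exaggerate the model's factor correlations and are non-zero
even where Phi is constrained to zero — is expected behaviour and is
asserted as such in the tests.

Tucker congruence between loading matrices matches columns by maximizing
total |congruence| over permutations with sign freedom; 0.85 is the
conventional similarity threshold, 0.95 near-identity.

## The synthetic cohorts

Genotypes: two iid haplotypes per individual, each obtained by thresholding
a latent Gaussian with AR(1) correlation inside LD blocks (50 SNPs per
block by default) and independence across blocks; blocks are assigned
round-robin to 22 autosome labels with 10 kb spacing; target allele
frequencies are uniform on (0.05, 0.5); monomorphic columns are redrawn.
The per-block AR(1) coefficient is drawn uniformly from (0.1, 0.98):
heterogeneous LD is both what genomes look like and what LD-score
regression needs — with a single rho the LD scores barely vary and the
regression slope is unidentified in practice.

Genetic architecture: one causal-SNP set shared by all traits, effects
drawn from a multivariate normal with the configured genetic-correlation
matrix and scaled so each trait's genetic value has variance exactly h²
(defaults 0.107, 0.057, 0.064).  The causal fraction defaults to 1.0
(dense/polygenic); with sparse causal sets the realized per-block signal is
noisy around the LD-score expectation and the block jackknife under-covers
(±2 SE coverage ≈ 80% instead of ≈ 95% in pilot runs), i.e. a dense
architecture is the regime in which LDSC's own model holds.  The fraction
remains a configuration knob.  Environmental residuals complete the target
phenotypic correlations (0, 0, 0.311 among the factors); auxiliary traits
(e.g. an income-like outcome with genetic correlations −0.39/0.15/0.17 to
the three factors) get independent environments.  Drawing the architecture
once and reusing it across cohorts makes the discovery and replication
cohorts samples from one population, which is what polygenic-score transfer
assumes.

Covariates are age ~ U(39, 73) and sex ~ Bernoulli(1/2), with zero effect
on the factors by default (configurable), so covariate adjustment is
exercised but does not distort the generative correlations.

What the generator does **not** emulate: realistic MAF spectra and
LD-versus-MAF coupling, population stratification (the LDSC intercept is
honest here by construction), relatedness, imputation uncertainty, X
chromosome, genotyping batch effects.  Passing tests therefore show the
estimators are correct and calibrated under the generative model — not that
the real-data quality-control pipeline is reproduced.

## GWAS

Factor scores are residualized on the covariate design (OLS; rank checked,
collinear columns named) and standardized; each SNP is then tested by
closed-form simple regression beta = cov(g, y)/var(g) with n−2 degrees of
freedom, identical to per-SNP OLS (asserted to 1e−10 against a
normal-equations oracle).  P-values use the normal tail — at the sample
sizes involved the t correction is far below any tolerance used.  Moments
of the dosage matrix are computed from {0,1,2} counts and the cross-product
in float64 chunks, so no float copy of the genotype matrix is made.

## LD-score regression

In-sample LD scores: l_j = sum over SNPs within a 1 Mb window of
r²_adj = r² − (1−r²)/(n−2), self-pair included (l_j ≥ 1).  Univariate
regression: chi²_j on n·l_j/M with free intercept, SNPs with chi² > 80 or
MAF < 0.01 removed first, standard two-component weights
(1 / [l_j · (1 + n·h²₀·l_j/M)²] with h²₀ the unweighted first-pass slope)
iterated once; the slope is h².  Bivariate: z_a·z_b on n·l_j/M, free
intercept (complete sample overlap shifts the intercept, not the slope);
rg = cov_g/sqrt(h²_a · h²_b), with the bivariate weights built from the
same h²₀ values as the univariate fits so that a trait regressed on itself
returns rg = 1 exactly.  Standard errors are delete-one block jackknives
over 200 contiguous SNP blocks; for rg the full ratio is re-estimated per
deleted block.  rg is reported as undefined (an error, or
a flagged NaN in the pipeline report) when either h² estimate is
non-positive.  The Benjamini–Hochberg step-up procedure supplies FDR flags
and adjusted p-values for correlation batteries.

## Genomic risk loci

The four-step definition: (1) genome-wide-significant SNPs (p < 5e−8) are
greedily thinned by ascending p so survivors are mutually at r² < 0.6
within ±1 Mb ("independent significant SNPs"); (2) input SNPs at r² ≥ 0.6
with a surviving SNP become locus members; (3) the survivors are thinned
again at r² < 0.1 to give lead SNPs; (4) lead SNPs closer than 250 kb are
merged single-linkage, non-lead independent SNPs attach to the cluster of
the lowest-p lead they tag at r² ≥ 0.1, and the locus border is the member
extreme positions; overlapping intervals on one chromosome are merged.
P-value ties break by (chromosome, position).  LD comes either from a
genotype matrix (computed on demand, cached) or a precomputed r² table; a
missing required pair is an error naming the pair.  Member SNPs are drawn
from the input summary statistics only (no external reference panel), so
borders can be narrower than a panel-based definition would give.

One property the algorithm does **not** have: the locus count is not
monotone in the significance threshold.  Tightening the threshold can drop
a bridging SNP and split a previously merged locus into two.  What is
monotone — and what the tests assert — is the SNP hierarchy: the
independent-significant and lead-SNP sets can only shrink when the
threshold tightens, because a SNP is only ever suppressed by SNPs with
lower p than its own.

## Polygenic scores

Score at cutoff t: sum over base-GWAS SNPs with p ≤ t of beta_j × dosage_j,
after allele matching (dosages re-oriented to the base effect allele;
strand-ambiguous A/T and C/G SNPs removed and logged; mismatched alleles
dropped); scores standardized per threshold; the five default cutoffs are
0.01, 0.05, 0.1, 0.5, 1.  No LD clumping is applied by default — the
synthetic panel is near-independent across blocks — but greedy clumping
(r² 0.1, 250 kb) is available.  Prediction regressions are OLS of the
(pre-residualized, standardized) phenotype on the score; the variance
explained beyond covariates equals the squared correlation in this design.

## Pipeline, sizes and numerics

The orchestrated pipeline simulates a discovery cohort (default n = 20,000)
and a replication cohort (n = 10,000) over M = 20,000 SNPs, fits the
measurement model in both, runs the three GWAS, the LDSC battery with FDR
flags, locus definition with cross-factor overlap counts, and the 3×3 PRS
prediction table; it writes results.json, a human-readable report and a
manifest (config hash, seed, library versions) and is byte-reproducible
for a fixed config and seed.  These problem sizes keep a full pipeline run
in minutes on one core while leaving every estimate's sampling error well
inside the tolerances the tests assert; the replicated experiments (LDSC
calibration, PRS specificity) use 20 seeded replicates each.

Degenerate inputs are errors with specific messages: constant items,
empty contingency margins, rank-deficient covariate designs, zero-variance
scores, LD scores without variation, fewer SNPs than jackknife blocks,
unsorted summary statistics.  Ties and sign freedoms are broken
deterministically everywhere (documented per module), so every experiment
is reproducible from its seed.

## Known limitations

* ULS-on-tetrachorics approximates the WLSMV-style estimation used by
  commercial SEM software; loadings agree to well within 0.05 at the sizes
  tested, but standard errors of loadings are not provided.
* The liability-scale/observed-scale distinction for binary items is
  sidestepped: GWAS phenotypes are (continuous) factor scores, as in the
  study design this mirrors.
* In-sample LD scores stand in for an external reference panel; with
  n = 20,000 the r² adjustment makes the error negligible, but tiny
  samples would attenuate the slope.
* The rg ratio is unstable when an h² estimate approaches zero; the
  package reports it as undefined rather than extrapolating.
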