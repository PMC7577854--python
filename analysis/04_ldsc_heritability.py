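"""LD-score regression: SNP heritability and genetic correlations.

Computes in-sample LD scores from the discovery genotypes, runs univariate
LDSC for each factor (chi2 > 80 and MAF < 0.01 filters, free intercept,
block jackknife) and bivariate LDSC for each factor pair, and prints a
heritability/genetic-correlation matrix (h2 on the diagonal, rg above) with
Benjamini-Hochberg FDR flags.
"""

import pathlib

import numpy as np
import pandas as pd

from neurofactors import io
from neurofactors import ldsc
from neurofactors.pipeline import FACTOR_NAMES
from neurofactors.simulate import simulate_genotypes

COHORTS = pathlib.Path("results/cohorts")
GWAS = pathlib.Path("results/gwas")
OUT = pathlib.Path("results/ldsc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = io.read_config_sidecar(COHORTS / "discovery_config.json")
    genotypes = simulate_genotypes(cfg)
    scores = ldsc.compute_ld_scores(genotypes)
    io.write_ldscores(scores, OUT / "discovery")

    sumstats = [io.read_sumstats(GWAS / f"sumstats_{t}.tsv", trait=t)
                for t in FACTOR_NAMES]
    fits = [ldsc.h2_regression(s, scores) for s in sumstats]
    pairs = [(0, 1), (0, 2), (1, 2)]
    rgs = {}
    for a, b in pairs:
        rgs[(a, b)] = ldsc.rg_regression(sumstats[a], sumstats[b], scores,
                                         fits[a], fits[b])
    flags, adj = ldsc.bh_fdr([rgs[p]["p"] for p in pairs])

    # h2 on the diagonal, genetic correlations above it
    table = pd.DataFrame("", index=FACTOR_NAMES, columns=FACTOR_NAMES)
    for i, fit in enumerate(fits):
        table.iloc[i, i] = f"{fit.h2:.1%} ({fit.se_h2:.1%})"
    for (a, b), flag in zip(pairs, flags):
        star = "*" if flag else ""
        table.iloc[a, b] = f"{rgs[(a, b)]['rg']:.2f} ({rgs[(a, b)]['se']:.2f}){star}"
    print("SNP heritability (diagonal) and genetic correlations (upper half);")
    print("* = significant after Benjamini-Hochberg FDR at q = 0.05")
    print(table.to_string())
    table.to_csv(OUT / "h2_rg_table.tsv", sep="\t")
    for i, fit in enumerate(fits):
        print(f"{FACTOR_NAMES[i]}: intercept {fit.intercept:.3f} "
              f"({fit.se_intercept:.3f}), {fit.snps_used} SNPs used")


if __name__ == "__main__":
    main()
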