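"""Polygenic-score replication and the direction-reversal experiment.

Two questions, mirroring the replication design of the pipeline:

1. Specificity: scores built from each discovery-cohort factor GWAS at five
   p-value cutoffs (0.01, 0.05, 0.1, 0.5, 1) should explain the most
   replication-cohort variance in the *same* factor.
2. Direction reversal: against an income-like outcome trait simulated with
   a negative genetic correlation with the general factor and positive
   genetic correlations with both special factors, the general-factor score
   should predict with a negative beta and the special-factor scores with
   positive betas.
"""

import pathlib

import numpy as np
import pandas as pd

from neurofactors import gwas as gw
from neurofactors import prs
from neurofactors.pipeline import FACTOR_NAMES
from neurofactors.simulate import (
    SimulationConfig,
    draw_architecture,
    simulate_factors,
    simulate_genotypes,
)

OUT = pathlib.Path("results/prs")
SEED = 1

# income-like outcome: genetic correlations with (general, anx/ten,
# worry/vuln) chosen to behave like household income
RG_OUTCOME = (-0.39, 0.15, 0.17)
H2_OUTCOME = 0.10


def four_trait_config(seed, n, m):
    rg = np.eye(4)
    rg[0, 1] = rg[1, 0] = 0.20
    rg[0, 2] = rg[2, 0] = 0.35
    rg[1, 2] = rg[2, 1] = 0.66
    rg[:3, 3] = rg[3, :3] = RG_OUTCOME
    return SimulationConfig(
        n_individuals=n, n_snps=m, h2=(0.107, 0.057, 0.064, H2_OUTCOME),
        rg_matrix=rg, seed=seed,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base_cfg = four_trait_config(SEED, 20_000, 10_000)
    targ_cfg = four_trait_config(SEED + 1_000_003, 10_000, 10_000)
    arch = draw_architecture(base_cfg)
    base_g = simulate_genotypes(base_cfg)
    base_f = simulate_factors(base_g, base_cfg, architecture=arch)
    targ_g = simulate_genotypes(targ_cfg)
    targ_f = simulate_factors(targ_g, targ_cfg, architecture=arch)

    sumstats = gw.run_gwas_multi(base_g, base_f.scores_true[:, :3], traits=FACTOR_NAMES)

    rows = []
    for f_base, ss in enumerate(sumstats):
        scores = prs.compute_prs(ss, targ_g)
        for f_tgt in range(4):
            pheno = targ_f.scores_true[:, f_tgt]
            best = max(
                (prs.prs_regression(scores[t].to_numpy(), pheno, threshold=float(t))
                 for t in scores.columns),
                key=lambda r: r.r2_increment,
            )
            rows.append({
                "score_from": FACTOR_NAMES[f_base],
                "predicting": (FACTOR_NAMES + ("income_like",))[f_tgt],
                "best_threshold": best.threshold,
                "beta": round(best.beta, 4),
                "r2_percent": round(100 * best.r2_increment, 3),
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "prediction.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    print("\nSpecificity: best R2 per score row should sit on the diagonal")
    for f_base in range(3):
        sub = table[(table.score_from == FACTOR_NAMES[f_base])
                    & (table.predicting != "income_like")]
        best_row = sub.loc[sub.r2_percent.idxmax()]
        marker = "OK" if best_row.predicting == FACTOR_NAMES[f_base] else "MISS"
        print(f"  {FACTOR_NAMES[f_base]:22s} -> {best_row.predicting:22s} [{marker}]")

    print("\nDirection reversal on the income-like outcome:")
    for f_base in range(3):
        row = table[(table.score_from == FACTOR_NAMES[f_base])
                    & (table.predicting == "income_like")].iloc[0]
        print(f"  {FACTOR_NAMES[f_base]:22s} beta = {row.beta:+.3f} "
              f"(R2 = {row.r2_percent:.3f}%)")


if __name__ == "__main__":
    main()
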