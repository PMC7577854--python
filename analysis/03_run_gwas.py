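"""Per-factor GWAS in the discovery cohort.

Factor scores are estimated from the fitted measurement model, residualized
on age and sex, standardized, and tested SNP-by-SNP under the additive
model.  Writes one summary-statistics TSV per factor plus a Manhattan plot.
"""

import pathlib

import numpy as np

from neurofactors import bifactor as bf
from neurofactors import gwas as gw
from neurofactors import io
from neurofactors.pipeline import FACTOR_NAMES
from neurofactors.simulate import draw_architecture, simulate_genotypes, simulate_factors

COHORTS = pathlib.Path("results/cohorts")
OUT = pathlib.Path("results/gwas")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = io.read_config_sidecar(COHORTS / "discovery_config.json")
    arch = draw_architecture(cfg)
    genotypes = simulate_genotypes(cfg)
    factors = simulate_factors(genotypes, cfg, architecture=arch)
    items = io.read_items(COHORTS / "discovery_items.tsv")
    model = io.read_model_json("results/bifactor/discovery_model.json")

    scores = bf.factor_scores(items, model)
    pheno = gw.residualize(scores, factors.covariates)
    sumstats = gw.run_gwas_multi(genotypes, pheno, traits=FACTOR_NAMES)
    for s in sumstats:
        io.write_sumstats(s, OUT / f"sumstats_{s.trait}.tsv")
        n_gw = int((s.table["P"] < 5e-8).sum())
        print(f"{s.trait}: {len(s)} SNPs tested, "
              f"{n_gw} genome-wide significant, min p = {s.table['P'].min():.2e}")
    _manhattan(sumstats)


def _manhattan(sumstats) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(10, 9), sharex=True)
    colors = ("tab:blue", "tab:orange", "tab:red")
    for ax, s, color in zip(axes, sumstats, colors):
        t = s.table.sort_values(["CHR", "BP"])
        x = np.arange(len(t))
        ax.scatter(x, -np.log10(t["P"]), s=2, c=np.where(t["CHR"] % 2, color, "grey"))
        ax.axhline(-np.log10(5e-8), color="red", lw=0.8)
        ax.axhline(-np.log10(1e-5), color="black", lw=0.8, ls=":")
        ax.set_ylabel(f"{s.trait}\n-log10 p")
    axes[-1].set_xlabel("SNP (genome order)")
    fig.tight_layout()
    fig.savefig(OUT / "manhattan.png", dpi=120)
    print(f"Manhattan plot: {OUT/'manhattan.png'}")


if __name__ == "__main__":
    main()
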