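"""Readers and writers for every pipeline artefact.

Conventions: positions are 1-based internally and in TSV/VCF output; BED
output is 0-based half-open.  Genotypes round-trip through gzip TSV
(snp, chr, bp, a1, a2, then one dosage column per individual) or a minimal
VCF 4.2 with GT hard calls.  Every writer's output is parseable by the
matching reader with lossless field equality.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas import GwasSummaryStats
from .ldsc import LDScoreTable
from .loci import Locus
from .simulate import GenotypeMatrix, ItemResponseMatrix, SimulationConfig

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "write_items",
    "read_items",
    "write_covariates",
    "read_covariates",
    "write_sumstats",
    "read_sumstats",
    "write_ldscores",
    "read_ldscores",
    "write_corr_matrix",
    "read_corr_matrix",
    "write_loci_bed",
    "write_loci_tsv",
    "read_loci_tsv",
    "write_model_json",
    "read_model_json",
    "write_config_sidecar",
    "read_config_sidecar",
]


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        samples = "\t".join(f"id{i + 1}" for i in range(genotypes.n_individuals))
        fh.write(f"snp\tchr\tbp\ta1\ta2\t{samples}\n")
        D = genotypes.dosages
        for j in range(genotypes.n_snps):
            row = "\t".join(map(str, D[:, j]))
            fh.write(
                f"{genotypes.snp_ids[j]}\t{genotypes.chrom[j]}\t{genotypes.bp[j]}\t"
                f"{genotypes.a1[j]}\t{genotypes.a2[j]}\t{row}\n"
            )


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", compression="infer")
    meta = df[["snp", "chr", "bp", "a1", "a2"]]
    D = df.drop(columns=["snp", "chr", "bp", "a1", "a2"]).to_numpy(dtype=np.int8).T
    freq = D.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=np.ascontiguousarray(D),
        snp_ids=meta["snp"].to_numpy(dtype=str),
        chrom=meta["chr"].to_numpy(dtype=np.int32),
        bp=meta["bp"].to_numpy(dtype=np.int64),
        a1=meta["a1"].to_numpy(dtype=str),
        a2=meta["a2"].to_numpy(dtype=str),
        maf=np.minimum(freq, 1.0 - freq),
    )


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with hard-call GT; a1 is written as ALT."""
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"id{i + 1}" for i in range(genotypes.n_individuals))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(genotypes.n_snps):
            gts = "\t".join(gt_map[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.bp[j]}\t{genotypes.snp_ids[j]}\t"
                f"{genotypes.a2[j]}\t{genotypes.a1[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a minimal VCF; counts ALT alleles in GT as the a1 dosage."""
    snp_ids, chrom, bp, a1, a2, rows = [], [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom.append(int(parts[0]))
            bp.append(int(parts[1]))
            snp_ids.append(parts[2])
            a2.append(parts[3])
            a1.append(parts[4])
            rows.append([gt.count("1") for gt in parts[9:]])
    D = np.asarray(rows, dtype=np.int8).T
    freq = D.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=np.ascontiguousarray(D),
        snp_ids=np.asarray(snp_ids),
        chrom=np.asarray(chrom, dtype=np.int32),
        bp=np.asarray(bp, dtype=np.int64),
        a1=np.asarray(a1),
        a2=np.asarray(a2),
        maf=np.minimum(freq, 1.0 - freq),
    )


# ---------------------------------------------------------------------------
# items / covariates


def write_items(items: ItemResponseMatrix, path) -> None:
    pd.DataFrame(items.responses, columns=list(items.item_labels)).to_csv(
        path, sep="\t", index=False
    )


def read_items(path) -> ItemResponseMatrix:
    df = pd.read_csv(path, sep="\t")
    return ItemResponseMatrix(
        responses=df.to_numpy(dtype=np.int8), item_labels=tuple(df.columns)
    )


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# summary statistics / LD scores


def write_sumstats(sumstats: GwasSummaryStats, path) -> None:
    sumstats.table.to_csv(path, sep="\t", index=False)


def read_sumstats(path, trait: str = "") -> GwasSummaryStats:
    return GwasSummaryStats(table=pd.read_csv(path, sep="\t"), trait=trait)


def write_ldscores(ldscores: LDScoreTable, prefix) -> None:
    """Conventional layout: <prefix>.l2.ldscore (CHR SNP BP L2) + <prefix>.l2.M."""
    ldscores.table[["CHR", "SNP", "BP", "L2"]].to_csv(
        f"{prefix}.l2.ldscore", sep="\t", index=False
    )
    Path(f"{prefix}.l2.M").write_text(f"{ldscores.M}\n")


def read_ldscores(prefix) -> LDScoreTable:
    table = pd.read_csv(f"{prefix}.l2.ldscore", sep="\t")
    M = int(Path(f"{prefix}.l2.M").read_text().strip())
    return LDScoreTable(table=table, M=M)


# ---------------------------------------------------------------------------
# correlation matrix / model


def write_corr_matrix(corr: np.ndarray, labels, path) -> None:
    pd.DataFrame(corr, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_corr_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_model_json(model, path) -> None:
    payload = {
        "loadings": model.loadings.tolist(),
        "phi": model.phi.tolist(),
        "thresholds": None if model.thresholds is None else model.thresholds.tolist(),
        "uniqueness": None if model.uniqueness is None else model.uniqueness.tolist(),
        "fit": model.fit,
        "variance_explained": None
        if model.variance_explained is None
        else model.variance_explained.tolist(),
        "criterion_value": model.criterion_value,
        "rotation_meta": model.rotation_meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model_json(path):
    from .bifactor import BifactorModel

    d = json.loads(Path(path).read_text())
    return BifactorModel(
        loadings=np.asarray(d["loadings"]),
        phi=np.asarray(d["phi"]),
        thresholds=None if d["thresholds"] is None else np.asarray(d["thresholds"]),
        uniqueness=None if d["uniqueness"] is None else np.asarray(d["uniqueness"]),
        fit=d["fit"],
        variance_explained=None
        if d["variance_explained"] is None
        else np.asarray(d["variance_explained"]),
        criterion_value=d["criterion_value"],
        rotation_meta=d["rotation_meta"],
    )


# ---------------------------------------------------------------------------
# loci


def write_loci_bed(loci: list, path) -> None:
    """BED: 0-based half-open intervals converted from 1-based inclusive."""
    with open(path, "w") as fh:
        for i, loc in enumerate(loci):
            c, start, end = loc.to_bed()
            fh.write(f"chr{c}\t{start}\t{end}\tlocus{i + 1}\n")


def write_loci_tsv(loci: list, path) -> None:
    rows = [
        {
            "locus": i + 1,
            "chrom": loc.chrom,
            "start_bp": loc.start_bp,
            "end_bp": loc.end_bp,
            "lead_snps": ",".join(loc.lead_snps),
            "independent_significant_snps": ",".join(loc.independent_significant_snps),
            "n_member_snps": len(loc.member_snps),
            "member_snps": ",".join(loc.member_snps),
        }
        for i, loc in enumerate(loci)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        Locus(
            chrom=int(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            lead_snps=str(r.lead_snps).split(","),
            independent_significant_snps=str(r.independent_significant_snps).split(","),
            member_snps=str(r.member_snps).split(","),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# config sidecar


def write_config_sidecar(config: SimulationConfig, path) -> None:
    payload = {
        "n_individuals": config.n_individuals,
        "n_snps": config.n_snps,
        "maf_range": list(config.maf_range),
        "ld_block_size": config.ld_block_size,
        "ld_rho": config.ld_rho,
        "h2": list(config.h2),
        "rg_matrix": config.rg_matrix.tolist(),
        "phi_special": config.phi_special,
        "loading_matrix": config.loading_matrix.tolist(),
        "item_thresholds": config.item_thresholds.tolist(),
        "n_causal_frac": config.n_causal_frac,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_config_sidecar(path) -> SimulationConfig:
    d = json.loads(Path(path).read_text())
    return SimulationConfig(
        n_individuals=d["n_individuals"],
        n_snps=d["n_snps"],
        maf_range=tuple(d["maf_range"]),
        ld_block_size=d["ld_block_size"],
        ld_rho=d["ld_rho"],
        h2=tuple(d["h2"]),
        rg_matrix=np.asarray(d["rg_matrix"]),
        phi_special=d["phi_special"],
        loading_matrix=np.asarray(d["loading_matrix"]),
        item_thresholds=np.asarray(d["item_thresholds"]),
        n_causal_frac=d["n_causal_frac"],
        seed=d["seed"],
    )
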