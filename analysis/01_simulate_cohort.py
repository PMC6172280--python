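#!/usr/bin/env python
"""Generate the synthetic study cohort.

One 1 Mb locus of 60 SNPs carrying four genes, two expression reference
panels (500 and 300 samples), an LD reference panel of 489 samples, and
GWAS summary statistics for 142,392 samples in which the trait is driven by
cis-regulated expression of the first gene (GWAS chi-square ~ 40 at the
causal gene).  Everything is written in the formats the pipeline consumes:
a PLINK fileset per cohort, expression and covariate TSVs, a gene index,
and a summary-statistic TSV.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from twaskit import plink
from twaskit.expression_models import inverse_normal_transform
from twaskit.reporting import write_tsv
from twaskit.sumstats import save_sumstats
from twaskit.synthetic_data import (
    SimConfig,
    config_to_yaml,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_sumstats,
)

GENES = ["GENE1", "GENE2", "GENE3", "GENE4"]  # GENE1 is causal
PANELS = {"panelA": 500, "panelB": 300}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed, p=60)
    config_to_yaml(cfg, out / "config.yaml")
    rng = np.random.default_rng(cfg.seed)

    # gene index: four TSSs spread across the locus
    tss = [700_000, 850_000, 1_100_000, 1_300_000]
    gene_index = pd.DataFrame(
        {"gene": GENES, "chrom": "1", "tss": tss, "strand": "+"}
    )
    write_tsv(gene_index, out / "gene_index.tsv")

    # LD reference panel
    ld_ref = simulate_genotypes(cfg, n=cfg.n_ref, p=cfg.p, rng=rng)
    bim = ld_ref.snps.copy()
    bim["cm"] = 0
    plink.write_bed(out / "ld_reference", ld_ref.dosages, bim)

    # true cis architecture shared across panels: one weight vector per gene
    arch_rng = np.random.default_rng(cfg.seed + 1)
    true_w = {}
    for k, gene in enumerate(GENES):
        w = np.zeros(cfg.p)
        causal = arch_rng.choice(cfg.p, size=cfg.k_causal_snps, replace=False)
        w[causal] = arch_rng.standard_normal(cfg.k_causal_snps)
        true_w[gene] = w

    # expression panels: own genotypes, same architecture, noisy expression
    for panel, n in PANELS.items():
        g = simulate_genotypes(cfg, n=n, p=cfg.p, rng=rng)
        plink.write_bed(out / f"{panel}_genotypes", g.dosages, bim.assign(), None)
        Z = g.standardized()
        expr = {}
        for gene in GENES:
            genetic = Z @ true_w[gene]
            genetic /= genetic.std()
            noise = rng.standard_normal(n)
            noise -= genetic * (noise @ genetic) / (genetic @ genetic)
            y = np.sqrt(cfg.h2_expr) * genetic + np.sqrt(1 - cfg.h2_expr) * (noise / noise.std())
            expr[gene] = inverse_normal_transform(y)
        expr_df = pd.DataFrame(expr, index=g.samples).T
        expr_df.insert(0, "gene", expr_df.index)
        expr_df.to_csv(out / f"{panel}_expression.tsv", sep="\t", index=False)
        cov = pd.DataFrame(
            {
                "sample": g.samples,
                "sex": rng.integers(0, 2, size=n),
                "age": rng.normal(55, 8, size=n).round(1),
            }
        )
        write_tsv(cov, out / f"{panel}_covariates.tsv")

    # GWAS summary statistics: trait acts through GENE1's cis expression
    alpha = np.sqrt(40.0 / cfg.n_gwas)
    ss = simulate_gwas_sumstats(
        ld_ref, true_w["GENE1"], alpha, cfg.n_gwas, seed=cfg.seed + 2, mode="summary"
    )
    save_sumstats(ss, out / "gwas_sumstats.tsv")

    truth = pd.DataFrame({"snp": ld_ref.snps["snp"]})
    for gene in GENES:
        truth[gene] = true_w[gene]
    write_tsv(truth, out / "true_weights.tsv")
    chi2 = (ss.table["z"] ** 2).max()
    print(f"wrote cohort to {out}")
    print(f"  locus: {cfg.p} SNPs, genes at TSS {tss}")
    print(f"  panels: {PANELS}, LD reference n = {cfg.n_ref}")
    print(f"  GWAS n = {cfg.n_gwas}; max SNP chi-square = {chi2:.1f}")


if __name__ == "__main__":
    main()
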