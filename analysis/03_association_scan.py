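#!/usr/bin/env python
"""Summary-based TWAS scan over all trained gene x panel models.

QCs and harmonizes the GWAS summary statistics against the LD reference,
computes z_TWAS = w'z / sqrt(w'Vw) for every model, applies Bonferroni
correction at 0.05 / (number of models), runs the adaptive permutation test
for significant models, and writes the association table and a Manhattan-
style plot.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from twaskit.expression_models import GeneModel, load_weights
from twaskit.ld_reference import compute_ld, load_genotypes
from twaskit.reporting import manhattan_plot, write_tsv
from twaskit.sumstats import harmonize_alleles, load_sumstats, qc_sumstats
from twaskit.twas import (
    association_scan,
    bonferroni_threshold,
    permutation_test,
    results_frame,
    stronger_than_gwas,
    p_to_z,
)


def load_models(model_dir: Path):
    models = []
    for path in sorted(model_dir.glob("*.weights.tsv")):
        panel, gene, _, _ = path.name.split(".")
        w = load_weights(path)
        models.append(
            GeneModel(
                gene=gene, panel=panel, snps=w[["snp", "a1", "a2"]],
                weights=w["weight"].to_numpy(), model_label="trained",
                cv_r2=float("nan"), cv_p=float("nan"),
            )
        )
    return models


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--models", type=Path, default=Path("results/models"))
    ap.add_argument("--out", type=Path, default=Path("results/twas"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno = load_genotypes(args.data / "ld_reference")
    ld = compute_ld(geno, ridge=0.1)
    ss = load_sumstats(args.data / "gwas_sumstats.tsv")
    ss = qc_sumstats(ss)
    ss = harmonize_alleles(ss, geno.snps[["snp", "a1", "a2"]])

    models = load_models(args.models)
    gene_index = pd.read_csv(args.data / "gene_index.tsv", sep="\t").set_index("gene")
    tss = gene_index["tss"].to_dict()
    results = association_scan(models, ss, geno, gene_tss=tss)

    threshold = bonferroni_threshold(0.05, len(models))
    z_by_snp = ss.table.set_index("snp")["z"]
    rows = results_frame(results)
    rows["tss"] = rows["gene"].map(tss)
    rows["significant"] = rows["p_twas"] < threshold
    rows["stronger_than_gwas"] = [
        stronger_than_gwas(r.z_twas, p_to_z(r.best_gwas_p, 1) if r.best_gwas_p else None)
        for r in results
    ]

    # permutation test for significant models
    perm_p, perm_n = [], []
    snp_pos = {s: i for i, s in enumerate(ld.snp_ids)}
    zvec = ss.table["z"].to_numpy()
    for r, m in zip(results, models):
        if r.p_twas < threshold:
            present = [(j, snp_pos[s]) for j, s in enumerate(m.snps["snp"]) if s in snp_pos]
            jj = [j for j, _ in present]
            idx = [i for _, i in present]
            pr = permutation_test(
                m.weights[jj], zvec[idx], ld.V[np.ix_(idx, idx)], seed=args.seed
            )
            perm_p.append(pr.perm_p)
            perm_n.append(pr.perm_n)
        else:
            perm_p.append(float("nan"))
            perm_n.append(0)
    rows["perm_p"] = perm_p
    rows["perm_n"] = perm_n

    write_tsv(rows, args.out / "associations.tsv")
    manhattan_plot(rows, args.out / "manhattan.png", threshold=threshold)
    print(f"Bonferroni threshold 0.05/{len(models)} = {threshold:.3g}")
    cols = ["gene", "panel", "z_twas", "p_twas", "significant", "perm_p", "best_gwas_p"]
    print(rows[cols].to_string(index=False))


if __name__ == "__main__":
    main()
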