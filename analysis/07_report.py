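#!/usr/bin/env python
"""Cross-panel summaries: mean chi-square, cross-tissue similarity, overlap.

Summarizes per-panel TWAS signal (mean chi-square with MAD-based SD),
measures cross-panel similarity of predicted expression by predicting both
panels' models into the LD reference cohort, and tests overlap between the
significant genes and an externally 'reported' gene list with the one-sided
exact test.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from twaskit.ld_reference import load_genotypes
from twaskit.reporting import (
    cross_tissue_r2,
    overlap_enrichment,
    panel_chi2_barplot,
    panel_mean_chi2,
    write_tsv,
)

from importlib import import_module
import sys

sys.path.insert(0, str(Path(__file__).parent))
load_models = import_module("03_association_scan").load_models


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--models", type=Path, default=Path("results/models"))
    ap.add_argument("--twas", type=Path, default=Path("results/twas"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    assoc = pd.read_csv(args.twas / "associations.tsv", sep="\t")
    summaries = panel_mean_chi2(assoc, significance_threshold=0.05 / len(assoc))
    write_tsv(
        pd.DataFrame([s.__dict__ for s in summaries]), args.out / "panel_chi2.tsv"
    )
    panel_chi2_barplot(summaries, args.out / "panel_chi2.png")
    for s in summaries:
        print(
            f"{s.panel}: {s.n_models} models, mean chi2 = {s.mean_chi2:.2f} "
            f"(MAD-SD {s.mad_sd:.2f}), {s.n_significant} significant"
        )

    # cross-panel similarity: predict every model into the LD reference cohort
    geno = load_genotypes(args.data / "ld_reference")
    Z = geno.standardized()
    order = {s: i for i, s in enumerate(geno.snps["snp"])}
    preds: dict[str, dict[str, np.ndarray]] = {}
    for m in load_models(args.models):
        w = np.zeros(geno.p)
        for j, sid in enumerate(m.snps["snp"]):
            if sid in order:
                w[order[sid]] = m.weights[j]
        preds.setdefault(m.panel, {})[m.gene] = Z @ w
    if len(preds) >= 2:
        frames = {p: pd.DataFrame(d) for p, d in preds.items()}
        table, per_gene, per_pair = cross_tissue_r2(frames)
        write_tsv(table, args.out / "cross_tissue_r2.tsv")
        print(f"cross-panel predicted-expression R2 (mean) = {table['r2'].mean():.2f}")

    # overlap of significant genes with a synthetic 'previously reported' list
    genes = sorted(assoc["gene"].unique())
    sig_genes = set(assoc.loc[assoc["significant"], "gene"])
    reported = {g for g in genes if g in sig_genes} | {genes[-1]}
    a = np.array([g in reported for g in genes])
    b = np.array([g in sig_genes for g in genes])
    table2x2, p = overlap_enrichment(a, b, universe=len(genes))
    print(f"overlap table {table2x2.tolist()}; one-sided exact P = {p:.3g}")


if __name__ == "__main__":
    main()
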