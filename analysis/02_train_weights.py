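#!/usr/bin/env python
"""Estimate cis-heritability and train predictive weights per gene x panel.

Reads the cohort written by 01_simulate_cohort.py, residualizes covariates,
keeps genes with nominally significant cis-h2 (P < 0.05), trains the model
menu (ridge-BLUP, LASSO, elastic net, top eQTL) with fivefold CV, and
writes one weight TSV per trained gene plus a panel manifest with h2, its
P-value, the chosen model, cross-validation R^2, and normalized accuracy.
"""

import argparse
from pathlib import Path

import pandas as pd

from twaskit.expression_models import (
    estimate_cis_h2,
    normalized_accuracy,
    save_weights,
    train_weights,
)
from twaskit.ld_reference import load_genotypes
from twaskit.reporting import write_tsv

PANELS = ["panelA", "panelB"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/models"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    manifest = []
    for panel in PANELS:
        geno = load_genotypes(args.data / f"{panel}_genotypes")
        expr = pd.read_csv(args.data / f"{panel}_expression.tsv", sep="\t").set_index("gene")
        cov = pd.read_csv(args.data / f"{panel}_covariates.tsv", sep="\t")
        C = cov[["sex", "age"]].to_numpy(dtype=float)
        for gene, row in expr.iterrows():
            y = row.to_numpy(dtype=float)
            h2 = estimate_cis_h2(y, geno, C=C)
            heritable = h2.p_value < 0.05
            model = None
            if heritable:
                model = train_weights(
                    y, geno, C=C, seed=args.seed, gene=gene, panel=panel, h2=h2
                )
            if model is not None:
                save_weights(model, args.out / f"{panel}.{gene}.weights.tsv")
            manifest.append(
                {
                    "gene": gene,
                    "panel": panel,
                    "h2": round(h2.h2, 4),
                    "h2_p": h2.p_value,
                    "heritable": heritable,
                    "model": model.model_label if model else "untrainable",
                    "cv_r2": model.cv_r2 if model else float("nan"),
                    "cv_p": model.cv_p if model else float("nan"),
                    "norm_accuracy": (
                        normalized_accuracy(model.cv_r2, h2.h2) if model and h2.h2 > 0 else float("nan")
                    ),
                }
            )
    mf = pd.DataFrame(manifest)
    write_tsv(mf, args.out / "manifest.tsv")
    trained = mf[mf["model"] != "untrainable"]
    print(f"trained {len(trained)}/{len(mf)} gene x panel models")
    print(mf.to_string(index=False))


if __name__ == "__main__":
    main()
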