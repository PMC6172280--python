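#!/usr/bin/env python
"""Conditional GWAS analysis at the locus, given predicted expression.

Conditions the SNP-level GWAS Z-scores on the predicted expression of the
most significant TWAS gene and reports how much of the association signal
the gene explains (lead-SNP marginal vs conditional P), with a locus plot.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from twaskit.conditional import condition_on_models
from twaskit.ld_reference import compute_ld, load_genotypes
from twaskit.reporting import conditional_locus_plot, write_tsv
from twaskit.sumstats import harmonize_alleles, load_sumstats, qc_sumstats
from twaskit.twas import twas_zscore, z_to_p

from importlib import import_module
import sys

sys.path.insert(0, str(Path(__file__).parent))
load_models = import_module("03_association_scan").load_models


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--models", type=Path, default=Path("results/models"))
    ap.add_argument("--twas", type=Path, default=Path("results/twas"))
    ap.add_argument("--out", type=Path, default=Path("results/conditional"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno = load_genotypes(args.data / "ld_reference")
    ld = compute_ld(geno, ridge=0.1)
    ss = harmonize_alleles(
        qc_sumstats(load_sumstats(args.data / "gwas_sumstats.tsv")),
        geno.snps[["snp", "a1", "a2"]],
    )
    zvec = ss.table["z"].to_numpy()

    assoc = pd.read_csv(args.twas / "associations.tsv", sep="\t")
    top = assoc.loc[assoc["p_twas"].idxmin()]
    models = [
        m for m in load_models(args.models)
        if m.gene == top["gene"] and m.panel == top["panel"]
    ]
    z_twas = np.array([twas_zscore(m.weights, zvec, ld)[0] for m in models])

    res = condition_on_models(zvec, models, ld, z_twas)
    table = pd.DataFrame(
        {
            "snp": res.snp_ids,
            "chrom": ss.table["chrom"],
            "pos": ss.table["pos"],
            "z_marginal": res.z_marginal,
            "p_marginal": [z_to_p(z) for z in res.z_marginal],
            "z_conditional": res.z_conditional,
            "p_conditional": [z_to_p(z) for z in res.z_conditional],
            "fully_explained": res.fully_explained,
            "genes_conditioned": ",".join(res.genes_conditioned),
        }
    )
    write_tsv(table, args.out / "conditional.tsv")
    conditional_locus_plot(res, ss.table["pos"], args.out / "locus.png")

    lead = table.loc[table["p_marginal"].idxmin()]
    print(f"conditioned on predicted expression of {top['gene']} ({top['panel']})")
    print(
        f"lead SNP {lead['snp']}: marginal P = {lead['p_marginal']:.3g}, "
        f"conditional P = {lead['p_conditional']:.3g}"
    )


if __name__ == "__main__":
    main()
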