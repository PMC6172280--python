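"""Cross-panel summaries, overlap tests, and figure outputs.

Panel-level signal is summarized by the mean TWAS chi-square with a robust
standard deviation (1.4826 x the median absolute deviation, the normal-
consistent scaling).  Cross-tissue similarity of gene models is the squared
Pearson correlation of their predictions on a shared cohort.  Overlap with
previously reported gene lists is tested with a one-sided hypergeometric
(Fisher) exact test in the enrichment direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from twaskit.exceptions import ValidationError

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass
class PanelSummary:
    panel: str
    n_models: int
    mean_chi2: float
    mad_sd: float
    n_significant: int


def panel_mean_chi2(
    results: pd.DataFrame,
    significance_threshold: float | None = None,
    significant_only: bool = False,
) -> list[PanelSummary]:
    """Per-panel mean chi-square (z_twas^2) with MAD-based SD.

    ``results`` needs columns (panel, z_twas, p_twas).  With
    ``significant_only`` the mean is restricted to models passing
    ``significance_threshold``.  Empty panels are skipped.
    """
    out = []
    for panel, grp in results.groupby("panel"):
        if grp.empty:
            continue
        chi2 = grp["z_twas"].to_numpy() ** 2
        n_sig = (
            int((grp["p_twas"] < significance_threshold).sum())
            if significance_threshold is not None
            else 0
        )
        if significant_only:
            if significance_threshold is None:
                raise ValidationError("significant_only needs a threshold")
            chi2 = grp.loc[grp["p_twas"] < significance_threshold, "z_twas"].to_numpy() ** 2
            if chi2.size == 0:
                continue
        mad = float(np.median(np.abs(chi2 - np.median(chi2))))
        out.append(
            PanelSummary(
                panel=str(panel),
                n_models=len(grp),
                mean_chi2=float(np.mean(chi2)),
                mad_sd=MAD_SCALE * mad,
                n_significant=n_sig,
            )
        )
    return out


def cross_tissue_r2(
    predictions: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Squared Pearson correlation of per-gene predictions across panel pairs.

    ``predictions`` maps panel id -> (samples x genes) prediction matrix on a
    shared cohort.  Returns (per gene-pair table, per-gene averages,
    per-panel-pair averages).  Zero-variance predictions are skipped.
    """
    panels = sorted(predictions)
    if len(panels) < 2:
        raise ValidationError("need at least two panels")
    rows = []
    for i, pa in enumerate(panels):
        for pb in panels[i + 1:]:
            shared = predictions[pa].columns.intersection(predictions[pb].columns)
            for gene in shared:
                a = predictions[pa][gene].to_numpy(dtype=float)
                b = predictions[pb][gene].to_numpy(dtype=float)
                if np.std(a) == 0 or np.std(b) == 0:
                    continue
                r = float(np.corrcoef(a, b)[0, 1])
                rows.append({"panel_a": pa, "panel_b": pb, "gene": gene, "r2": r**2})
    if not rows:
        raise ValidationError("no gene shared between any pair of panels")
    table = pd.DataFrame(rows)
    per_gene = table.groupby("gene", as_index=False)["r2"].mean()
    per_pair = table.groupby(["panel_a", "panel_b"], as_index=False)["r2"].mean()
    return table, per_gene, per_pair


def overlap_enrichment(
    set_a: np.ndarray,
    set_b: np.ndarray,
    universe: int,
) -> tuple[np.ndarray, float]:
    """2x2 overlap table and one-sided hypergeometric enrichment P.

    ``set_a`` and ``set_b`` are boolean flags over the same gene list (or any
    iterables of bools); ``universe`` is the total number of genes and must
    cover the union.  The table is [[both, a_only], [b_only, neither]] and
    the P-value is Pr(overlap >= observed) under random draws.
    """
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("flag vectors must align")
    both = int((a & b).sum())
    return overlap_enrichment_counts(both, int(a.sum()), int(b.sum()), universe)


def overlap_enrichment_counts(
    n_overlap: int, n_a: int, n_b: int, universe: int
) -> tuple[np.ndarray, float]:
    """Overlap test from marginal counts; see :func:`overlap_enrichment`."""
    a_only = n_a - n_overlap
    b_only = n_b - n_overlap
    neither = universe - n_a - n_b + n_overlap
    if min(n_overlap, a_only, b_only, neither) < 0:
        raise ValidationError(
            f"inconsistent counts: overlap={n_overlap}, |a|={n_a}, |b|={n_b}, "
            f"universe={universe}"
        )
    table = np.array([[n_overlap, a_only], [b_only, neither]])
    p = float(hypergeom.sf(n_overlap - 1, universe, n_a, n_b))
    return table, p


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------- figures

def manhattan_plot(results: pd.DataFrame, path, threshold: float | None = None):
    """One point per gene model: -log10 P against TSS position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    x = results["tss"] if "tss" in results.columns else np.arange(len(results))
    ax.scatter(x, -np.log10(results["p_twas"]), s=8, c="#33557a")
    if threshold is not None:
        ax.axhline(-np.log10(threshold), ls="--", c="grey", lw=1)
    ax.set_xlabel("TSS position (bp)")
    ax.set_ylabel(r"$-\log_{10} P_{\mathrm{TWAS}}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def conditional_locus_plot(cond, positions, path, gwas_alpha: float = 5e-8):
    """Marginal vs conditional SNP association at one locus."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    fig, ax = plt.subplots(figsize=(7, 3.2))
    p_marg = 2 * norm.sf(np.abs(cond.z_marginal))
    p_cond = 2 * norm.sf(np.abs(cond.z_conditional))
    ax.scatter(positions, -np.log10(p_marg), s=10, c="grey", label="marginal")
    ax.scatter(positions, -np.log10(p_cond), s=10, c="#2a9d55", label="conditional")
    ax.axhline(-np.log10(gwas_alpha), ls="--", c="grey", lw=1)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def panel_chi2_barplot(summaries: list[PanelSummary], path):
    """Per-panel mean chi-square bars with MAD-based SD whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(summaries)), 3.2))
    names = [s.panel for s in summaries]
    means = [s.mean_chi2 for s in summaries]
    errs = [s.mad_sd for s in summaries]
    ax.bar(names, means, yerr=errs, capsize=3, color="#7a8fb5")
    ax.set_ylabel(r"mean $\chi^2$")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
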