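"""Risk-region partitioning, novelty flags, and Bayesian gene prioritization.

Under a single-causal-gene model per region with a normal prior on the
gene-trait effect (variance sigma_a^2), the evidence that gene i drives the
region is

    BF_i = N(z_i | 0, 1 + n sigma_a^2) / N(z_i | 0, 1)
         = (1 + n sigma_a^2)^(-1/2) exp( (z_i^2 / 2) * n sigma_a^2 / (1 + n sigma_a^2) )

with n the GWAS sample size.  Posteriors normalize BFs within the region,
and a rho-credible gene set is built greedily by descending posterior until
cumulative mass reaches rho.

The prior scale n*sigma_a^2 defaults to 30 (prior expected chi-square of a
causal gene ~ 31); an empirical-Bayes alternative sets it to
max(0, mean(z^2) - 1) over transcriptome-wide-significant genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax

from twaskit.exceptions import ValidationError
from twaskit.sumstats import SumStats

DEFAULT_N_SIGMA_A2 = 30.0
GWAS_ALPHA = 5e-8


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    members: pd.DataFrame  # columns: gene, panel, tss, z_twas (panel optional)
    contains_gwas_hit: bool | None = None
    is_novel: bool | None = None
    no_snps_in_flank: bool = False


@dataclass
class CredibleSet:
    region: Region | None
    gene_ids: list[str]  # one per model in the region
    log_bfs: np.ndarray
    posteriors: np.ndarray
    rho: float
    members: list[int]  # indices ordered by descending posterior
    achieved_density: float

    @property
    def member_genes(self) -> list[str]:
        return [self.gene_ids[i] for i in self.members]

    @property
    def unique_member_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.member_genes:
            seen.setdefault(g, None)
        return list(seen)


def partition_regions(
    genes: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> list[Region]:
    """Greedy partition of significant gene models into TSS-centered regions.

    Sorts by (chrom, tss); each unassigned gene seeds a window of total span
    ``window_bp`` centered on its TSS and absorbs every gene within
    window_bp/2 of the seed.  Regions never overlap in membership.
    """
    required = {"gene", "tss", "chrom"}
    if not required.issubset(genes.columns):
        raise ValidationError(f"gene table needs columns {sorted(required)}")
    g = genes.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    half = window_bp // 2
    regions: list[Region] = []
    assigned = np.zeros(len(g), dtype=bool)
    for i in range(len(g)):
        if assigned[i]:
            continue
        seed_tss = int(g.loc[i, "tss"])
        chrom = g.loc[i, "chrom"]
        mask = (
            (~assigned)
            & (g["chrom"] == chrom)
            & (g["tss"] - seed_tss).abs().le(half)
        )
        members = g.loc[mask].reset_index(drop=True)
        assigned |= mask.to_numpy()
        regions.append(
            Region(
                chrom=str(chrom),
                start=max(seed_tss - half, 0),
                end=seed_tss + half,
                members=members,
            )
        )
    return regions


def flag_novel_regions(
    regions: list[Region],
    ss: SumStats,
    gwas_alpha: float = GWAS_ALPHA,
    flank_bp: int = 1_000_000,
) -> list[Region]:
    """Mark regions with no genome-wide-significant SNP near any member gene.

    A region is novel iff no SNP with P < ``gwas_alpha`` lies within
    TSS +/- ``flank_bp`` of any member gene.  Regions whose flanks contain no
    SNPs at all are flagged novel with ``no_snps_in_flank`` set.
    """
    t = ss.table
    pvals = ss.pvalues()
    for region in regions:
        any_snp = False
        any_hit = False
        on_chrom = t["chrom"] == region.chrom
        for tss in region.members["tss"]:
            window = on_chrom & t["pos"].between(int(tss) - flank_bp, int(tss) + flank_bp)
            if window.any():
                any_snp = True
                if (pvals[window.to_numpy()] < gwas_alpha).any():
                    any_hit = True
                    break
        region.contains_gwas_hit = any_hit
        region.is_novel = not any_hit
        region.no_snps_in_flank = not any_snp
    return regions


def bayes_factor(z_twas: float, n: float, sigma_a2: float) -> float:
    """log Bayes factor that a gene with TWAS score z is the causal gene.

    Computed in log space; safe for |z| of order tens.
    """
    if n < 1 or sigma_a2 < 0:
        raise ValidationError("need n >= 1 and sigma_a2 >= 0")
    s = n * sigma_a2
    return float(-0.5 * np.log1p(s) + 0.5 * z_twas**2 * s / (1.0 + s))


def empirical_prior_scale(z_scores: np.ndarray) -> float:
    """Empirical-Bayes n*sigma_a2 = max(0, mean(z^2) - 1) over significant genes."""
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValidationError("need at least one z-score for the empirical prior")
    return float(max(0.0, np.mean(z**2) - 1.0))


def gene_posteriors(log_bfs: np.ndarray) -> np.ndarray:
    """Posterior causal probabilities: softmax of the log Bayes factors."""
    log_bfs = np.atleast_1d(np.asarray(log_bfs, dtype=float))
    if log_bfs.size == 0:
        raise ValidationError("region has no gene models")
    return softmax(log_bfs)


def credible_set(
    posteriors: np.ndarray,
    rho: float = 0.90,
    gene_ids: list[str] | None = None,
    log_bfs: np.ndarray | None = None,
    region: Region | None = None,
) -> CredibleSet:
    """Greedy rho-credible gene set: add genes by descending posterior.

    Ties break deterministically on gene id.  rho = 1.0 keeps every gene
    with positive posterior.
    """
    post = np.atleast_1d(np.asarray(posteriors, dtype=float))
    if not (0.0 < rho <= 1.0):
        raise ValidationError(f"rho must be in (0, 1], got {rho}")
    if abs(post.sum() - 1.0) > 1e-6:
        raise ValidationError("posteriors must sum to 1 within a region")
    gene_ids = gene_ids or [f"gene{i}" for i in range(post.size)]
    order = sorted(range(post.size), key=lambda i: (-post[i], gene_ids[i]))
    members: list[int] = []
    total = 0.0
    for i in order:
        if total >= rho - 1e-12:
            break
        if rho >= 1.0 and post[i] <= 0.0:
            continue
        members.append(i)
        total += float(post[i])
    return CredibleSet(
        region=region,
        gene_ids=list(gene_ids),
        log_bfs=np.asarray(log_bfs) if log_bfs is not None else np.log(np.clip(post, 1e-300, None)),
        posteriors=post,
        rho=rho,
        members=members,
        achieved_density=total,
    )


def region_credible_set(
    z_twas: np.ndarray,
    n: float,
    sigma_a2: float | None = None,
    rho: float = 0.90,
    gene_ids: list[str] | None = None,
    region: Region | None = None,
) -> CredibleSet:
    """Bayes factors -> posteriors -> credible set for one region's models."""
    z = np.atleast_1d(np.asarray(z_twas, dtype=float))
    if sigma_a2 is None:
        sigma_a2 = DEFAULT_N_SIGMA_A2 / n
    lbf = np.array([bayes_factor(zi, n, sigma_a2) for zi in z])
    post = gene_posteriors(lbf)
    return credible_set(post, rho=rho, gene_ids=gene_ids, log_bfs=lbf, region=region)


def summarize_credible_sets(sets: list[CredibleSet]) -> dict:
    """Unique-gene counts and set-size summaries across regions.

    The same gene entering through multiple panels counts once per set and
    once overall.
    """
    if not sets:
        raise ValidationError("no credible sets to summarize")
    sizes = [len(s.unique_member_genes) for s in sets]
    unique: dict[str, None] = {}
    for s in sets:
        for gene in s.unique_member_genes:
            unique.setdefault(gene, None)
    return {
        "n_regions": len(sets),
        "n_unique_genes": len(unique),
        "set_sizes": sizes,
        "mean_size": float(np.mean(sizes)),
        "median_size": float(np.median(sizes)),
        "n_single_gene": int(sum(s == 1 for s in sizes)),
    }
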