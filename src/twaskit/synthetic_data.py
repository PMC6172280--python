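"""Synthetic cohorts with the statistical structure the TWAS model assumes.

The generators emulate, at desk scale, the data the pipeline consumes:

- genotypes with local LD: latent Gaussians with AR(1) correlation are
  thresholded into two pseudo-haplotypes per sample, giving {0,1,2} dosages
  whose adjacent-SNP correlation tracks (with some attenuation from
  discretization) the target ``rho_ld``;
- cis-heritable expression: a sparse set of causal SNPs whose in-sample
  variance contribution equals ``h2_expr`` exactly, so heritability and
  weight-recovery tests have a known truth;
- GWAS summary statistics under a single-causal-gene mechanism, either by
  simulating an individual-level cohort and computing marginal Wald
  statistics, or by sampling z ~ MVN(sqrt(n) alpha V w~, V) directly;
- regions of correlated TWAS Z-scores, built from random sparse weight
  matrices over simulated LD (gene_corr = D^-1 W'V W D^-1, the
  predicted-expression correlation mechanism), for the credible-set
  calibration experiment.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from twaskit.exceptions import ValidationError
from twaskit.finemap import region_credible_set
from twaskit.ld_reference import GenotypeMatrix
from twaskit.sumstats import SumStats


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults follow the analysis setting: an LD reference of 489 samples
    (the 1000 Genomes European panel size), a GWAS of 142,392 samples, a
    well-powered expression panel of 500 (the real panels span 87-1264),
    cis loci of 50 QC-passing SNPs with moderate adjacent LD, sparse
    cis architecture (5 causal SNPs) at h2 = 0.4, and a causal-gene prior
    scale n*sigma_a2 = 30.
    """

    seed: int = 0
    n_ref: int = 489
    n_panel: int = 500
    n_gwas: int = 142_392
    p: int = 50
    rho_ld: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_expr: float = 0.4
    k_causal_snps: int = 5
    alpha_gene: float = 0.0168  # per-SD effect; n_gwas * alpha^2 ~ 40
    k_genes: int = 5
    sigma_a2: float = 30.0 / 142_392

    def __post_init__(self):
        if not 0.0 <= self.h2_expr <= 1.0:
            raise ValidationError("h2_expr must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not -1.0 < self.rho_ld < 1.0:
            raise ValidationError("rho_ld must lie in (-1, 1)")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _ar1_haplotypes(rng, n: int, p: int, rho: float) -> np.ndarray:
    h = np.empty((n, p))
    h[:, 0] = rng.standard_normal(n)
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, p):
        h[:, j] = rho * h[:, j - 1] + scale * rng.standard_normal(n)
    return h

def simulate_genotypes(
    cfg: SimConfig,
    n: int | None = None,
    p: int | None = None,
    rng=None,
    chrom: str = "1",
    start_bp: int = 500_000,
    span_bp: int = 1_000_000,
) -> GenotypeMatrix:
    """Dosage matrix with AR(1) local LD, thresholded from latent Gaussians.

    Two latent haplotypes per sample are thresholded at the normal quantile
    of each SNP's MAF; dosages are their sum.  SNP positions are evenly
    spaced over ``span_bp``; alleles are fixed A/G (never strand-ambiguous).
    """
    rng = _rng(cfg.seed if rng is None else rng)
    n = n or cfg.n_ref
    p = p or cfg.p
    maf = rng.uniform(*cfg.maf_range, size=p)
    thresh = ndtri(maf)
    hap1 = _ar1_haplotypes(rng, n, p, cfg.rho_ld) < thresh
    hap2 = _ar1_haplotypes(rng, n, p, cfg.rho_ld) < thresh
    dosages = (hap1.astype(float) + hap2.astype(float))
    step = max(span_bp // p, 1)
    snps = pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(p)],
            "chrom": chrom,
            "pos": start_bp + np.arange(p) * step,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)], snps=snps, dosages=dosages
    )


def simulate_expression(
    X,
    h2_expr: float,
    k_causal_snps: int,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expression with an exact in-sample genetic variance fraction.

    Picks ``k_causal_snps`` SNPs with normal effects on standardized
    genotypes, then rescales the genetic and environmental parts so that
    var(Xw) / var(y) equals ``h2_expr`` exactly in-sample.  Returns
    (y, true_w) with true_w on the standardized-genotype scale.
    """
    rng = _rng(seed)
    Z = X.standardized() if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    n, p = Z.shape
    if k_causal_snps > p:
        raise ValidationError(f"k_causal_snps = {k_causal_snps} exceeds p = {p}")
    if not 0.0 <= h2_expr <= 1.0:
        raise ValidationError("h2_expr must lie in [0, 1]")
    w = np.zeros(p)
    causal = rng.choice(p, size=k_causal_snps, replace=False)
    w[causal] = rng.standard_normal(k_causal_snps)
    g = Z @ w
    e = rng.standard_normal(n)
    e -= e.mean()
    if h2_expr == 0.0:
        return e / e.std(), np.zeros(p)
    g_sd = g.std()
    if g_sd == 0:
        raise ValidationError("degenerate genetic component (all-zero effects)")
    # orthogonalize noise against the genetic component in-sample so the
    # realized variance fraction is exactly h2_expr
    e -= g * (e @ g) / (g @ g)
    scale_g = np.sqrt(h2_expr) / g_sd
    if h2_expr == 1.0:
        return g * scale_g, w * scale_g
    y = g * scale_g + e * (np.sqrt(1.0 - h2_expr) / e.std())
    return y, w * scale_g


def simulate_gwas_sumstats(
    X_or_V,
    true_w: np.ndarray,
    alpha_gene: float,
    n_gwas: int,
    seed=0,
    mode: str = "summary",
    snps: pd.DataFrame | None = None,
    maf: np.ndarray | None = None,
) -> SumStats:
    """Marginal GWAS Z-scores under a trait driven by one gene's expression.

    mode="individual": draws a cohort of ``n_gwas`` from the genotype
    generator's output (``X_or_V`` must be a GenotypeMatrix of that size),
    forms the trait y = alpha * std(Xw) + e and computes per-SNP marginal
    Wald statistics.

    mode="summary": samples z ~ MVN(sqrt(n) * alpha * V w~, V) with
    w~ = w / sqrt(w'Vw) the V-standardized weights (``X_or_V`` is then an
    LD matrix or a GenotypeMatrix from which LD is computed).
    """
    rng = _rng(seed)
    true_w = np.asarray(true_w, dtype=float)
    if mode == "individual":
        if not isinstance(X_or_V, GenotypeMatrix):
            raise ValidationError("individual mode needs a GenotypeMatrix cohort")
        Z = X_or_V.standardized()
        n = Z.shape[0]
        g = Z @ true_w
        g_sd = g.std()
        if g_sd == 0 and alpha_gene != 0:
            raise ValidationError("causal gene has zero genetic variance")
        g_std = g / g_sd if g_sd > 0 else g
        noise_var = max(1.0 - alpha_gene**2, 1e-12)
        y = alpha_gene * g_std + rng.standard_normal(n) * np.sqrt(noise_var)
        y = (y - y.mean()) / y.std()
        r = (Z.T @ y) / n
        r = np.clip(r, -0.9999999, 0.9999999)
        z = np.sqrt(n - 2) * r / np.sqrt(1.0 - r**2)
        snp_table = X_or_V.snps
        maf_vals = X_or_V.maf
        n_out = n
    elif mode == "summary":
        if isinstance(X_or_V, GenotypeMatrix):
            from twaskit.ld_reference import compute_ld

            ld = compute_ld(X_or_V, ridge=0.0)
            V = ld.V
            snp_table = X_or_V.snps
            maf_vals = X_or_V.maf
        else:
            V = X_or_V.V if hasattr(X_or_V, "V") else np.asarray(X_or_V, float)
            snp_table = snps
            maf_vals = maf
        quad = float(true_w @ V @ true_w)
        if alpha_gene != 0 and quad <= 0:
            raise ValidationError("causal gene has zero predicted variance in V")
        mean = (
            np.sqrt(n_gwas) * alpha_gene * (V @ (true_w / np.sqrt(quad)))
            if alpha_gene != 0
            else np.zeros(V.shape[0])
        )
        L = np.linalg.cholesky(V + 1e-10 * np.eye(V.shape[0]))
        z = mean + L @ rng.standard_normal(V.shape[0])
        n_out = n_gwas
    else:
        raise ValidationError(f"unknown mode '{mode}'")

    if snp_table is None:
        p = z.size
        snp_table = pd.DataFrame(
            {
                "snp": [f"rs{j + 1}" for j in range(p)],
                "chrom": "1",
                "pos": 500_000 + np.arange(p) * 1000,
                "a1": "A",
                "a2": "G",
            }
        )
    if maf_vals is None:
        maf_vals = np.full(z.size, 0.25)
    table = snp_table[["snp", "chrom", "pos", "a1", "a2"]].copy().reset_index(drop=True)
    table["z"] = np.asarray(z, dtype=float)
    table["maf"] = np.asarray(maf_vals, dtype=float)
    table["n"] = float(n_out)
    ss = SumStats(table)
    ss.record(f"simulated_mode_{mode}", 0)
    return ss


def random_gene_correlation(
    cfg: SimConfig,
    rng,
    k_genes: int | None = None,
) -> np.ndarray:
    """Predicted-expression correlation matrix from sparse weights over LD.

    Simulates a reference panel of ``n_ref`` genotypes, draws a sparse weight
    column per gene, and returns gene_corr = D^-1 W'V W D^-1 with V the
    empirical LD — the mechanism by which co-localized gene models correlate.
    Redraws weights if any gene's predicted variance degenerates.
    """
    rng = _rng(rng)
    k = k_genes or cfg.k_genes
    g = simulate_genotypes(cfg, n=cfg.n_ref, rng=rng)
    Z = g.standardized()
    V = (Z.T @ Z) / g.n
    for _ in range(20):
        W = np.zeros((cfg.p, k))
        for j in range(k):
            causal = rng.choice(cfg.p, size=min(cfg.k_causal_snps, cfg.p), replace=False)
            W[causal, j] = rng.standard_normal(causal.size)
        quad = np.einsum("pg,pq,qg->g", W, V, W)
        if np.all(quad > 1e-10):
            break
    Dinv = 1.0 / np.sqrt(quad)
    corr = (W.T @ V @ W) * np.outer(Dinv, Dinv)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def simulate_twas_region(
    k_genes: int,
    gene_corr: np.ndarray,
    causal_index: int,
    n: int,
    sigma_a2: float,
    rng=0,
) -> np.ndarray:
    """TWAS Z-scores for one region under a single causal gene.

    Draws the causal effect lambda ~ N(0, sigma_a2) and then
    z ~ MVN(sqrt(n) * lambda * gene_corr[:, causal], gene_corr), so the
    causal gene's marginal z^2 has mean 1 + n*sigma_a2.
    """
    rng = _rng(rng)
    gene_corr = np.asarray(gene_corr, dtype=float)
    if gene_corr.shape != (k_genes, k_genes):
        raise ValidationError("gene_corr shape does not match k_genes")
    if not 0 <= causal_index < k_genes:
        raise ValidationError("causal_index out of range")
    lam = rng.normal(0.0, np.sqrt(sigma_a2))
    mean = np.sqrt(n) * lam * gene_corr[:, causal_index]
    L = np.linalg.cholesky(gene_corr + 1e-10 * np.eye(k_genes))
    return mean + L @ rng.standard_normal(k_genes)


def calibration_experiment(
    cfg: SimConfig,
    n_regions: int = 1000,
    rho_levels: tuple[float, ...] = (0.5, 0.9, 0.95),
    seed: int | None = None,
) -> pd.DataFrame:
    """Credible-set coverage over simulated single-causal-gene regions.

    For each region: draw a predicted-expression correlation matrix, pick
    the causal gene uniformly, sample TWAS Z-scores under the Bayes-factor
    generative model, compute posteriors with the matching prior scale, and
    record whether each rho-credible set contains the causal gene.

    Returns a table with one row per rho level: coverage (fraction of
    regions capturing the causal gene) and mean unique-gene set size.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    hits = {rho: 0 for rho in rho_levels}
    sizes = {rho: [] for rho in rho_levels}
    for _ in range(n_regions):
        corr = random_gene_correlation(cfg, rng)
        causal = int(rng.integers(cfg.k_genes))
        z = simulate_twas_region(
            cfg.k_genes, corr, causal, n=cfg.n_gwas, sigma_a2=cfg.sigma_a2, rng=rng
        )
        for rho in rho_levels:
            cs = region_credible_set(
                z, n=cfg.n_gwas, sigma_a2=cfg.sigma_a2, rho=rho,
                gene_ids=[f"g{j}" for j in range(cfg.k_genes)],
            )
            if causal in cs.members:
                hits[rho] += 1
            sizes[rho].append(len(cs.members))
    return pd.DataFrame(
        {
            "rho": list(rho_levels),
            "coverage": [hits[r] / n_regions for r in rho_levels],
            "mean_set_size": [float(np.mean(sizes[r])) for r in rho_levels],
            "n_regions": n_regions,
            "seed": cfg.seed if seed is None else seed,
        }
    )


def config_to_yaml(cfg: SimConfig, path) -> None:
    import yaml

    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    return SimConfig(**d)
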