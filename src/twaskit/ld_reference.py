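"""Reference genotypes and regularized LD (SNP correlation) matrices.

The LD matrix V enters both the TWAS denominator w'Vw and the conditional
analysis; a ridge term V <- (1 - lambda) corr(X) + lambda I keeps it positive
definite when the reference panel is small relative to the number of SNPs at
a locus.  The regularization weight is stored on the result so downstream
outputs can report it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from twaskit import plink
from twaskit.exceptions import EmptyRegionError, ValidationError

#: cis-window convention used across the pipeline: TSS +/- 1 Mb, closed
CIS_WINDOW_BP = 1_000_000


@dataclass
class GenotypeMatrix:
    """Dosage matrix for one locus: n samples x p SNPs, mean-imputed."""

    samples: list[str]
    snps: pd.DataFrame  # columns: snp, chrom, pos, a1, a2
    dosages: np.ndarray  # n x p, values in [0, 2]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def standardized(self) -> np.ndarray:
        """Columns centered and scaled to unit variance (ddof=0)."""
        Z = self.dosages - self.dosages.mean(axis=0)
        sd = Z.std(axis=0)
        if np.any(sd == 0):
            bad = self.snps["snp"].iloc[int(np.argmax(sd == 0))]
            raise ValidationError(f"constant genotype column for SNP {bad}")
        return Z / sd


@dataclass
class LDMatrix:
    """SNP correlation matrix for a locus with its regularization weight."""

    snps: pd.DataFrame
    V: np.ndarray
    ridge: float

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp"])


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a "chr:start-end" string into (chrom, start, end)."""
    chrom, span = region.split(":")
    start, end = span.split("-")
    return chrom, int(start), int(end)


def load_genotypes(
    prefix: str,
    region: tuple[str, int, int] | str | None = None,
    maf_min: float = 0.01,
) -> GenotypeMatrix:
    """Load PLINK dosages for SNPs in a closed base-pair interval.

    Missing genotypes are mean-imputed per SNP; SNPs with MAF below
    ``maf_min`` (computed before imputation) or with no variation are
    dropped, mirroring the summary-statistic QC floor.
    """
    bim = plink.read_bim(prefix)
    fam = plink.read_fam(prefix)
    if region is not None:
        if isinstance(region, str):
            region = parse_region(region)
        chrom, start, end = region
        mask = (bim["chrom"] == str(chrom)) & bim["pos"].between(start, end)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise EmptyRegionError(f"no SNPs in region {chrom}:{start}-{end}")
    else:
        idx = np.arange(len(bim))
    dosages = plink.read_bed(prefix, snp_indices=idx)
    snps = bim.iloc[idx][["snp", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)

    col_mean = np.nanmean(dosages, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(dosages))
    dosages[nan_r, nan_c] = col_mean[nan_c]

    freq = col_mean / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_min) & (dosages.std(axis=0) > 0)
    if not keep.any():
        raise EmptyRegionError(
            f"no polymorphic SNPs above MAF {maf_min} in requested region"
        )
    return GenotypeMatrix(
        samples=list(fam["iid"]),
        snps=snps.loc[keep].reset_index(drop=True),
        dosages=dosages[:, keep],
    )


def compute_ld(g: GenotypeMatrix, ridge: float = 0.1) -> LDMatrix:
    """Regularized SNP correlation matrix V = (1 - ridge) corr(X) + ridge I.

    For ridge > 0 the spectrum is bounded below by ridge, so V is invertible
    and every downstream quadratic form is finite.
    """
    if g.n < 2:
        raise ValidationError("need at least 2 samples to estimate LD")
    if not 0.0 <= ridge < 1.0:
        raise ValidationError(f"ridge weight must be in [0, 1), got {ridge}")
    Z = g.standardized()  # raises on constant columns, naming the SNP
    R = (Z.T @ Z) / g.n
    V = (1.0 - ridge) * R + ridge * np.eye(g.p)
    V = (V + V.T) / 2.0
    np.fill_diagonal(V, 1.0)
    return LDMatrix(snps=g.snps.copy(), V=V, ridge=ridge)
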