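# Methods

## Model and assumptions

The pipeline treats gene–trait association as a two-stage linear system.
Stage one trains, per gene and reference panel, a cis-window predictor of
expression from local SNP genotypes, `y_GE = Cβ + X w_GE + ε`, with the
cis window fixed at TSS ± 1 Mb (closed, 1-based positions as in PLINK bim
files). Stage two never touches individual-level GWAS data: the association
between *predicted* expression and the trait is computed from GWAS summary
Z-scores and reference LD alone, `z_TWAS = w'z / √(w'Vw)`. This is exact
when the GWAS cohort and the LD reference share ancestry and the summary
statistics are Wald statistics on standardized genotypes; mismatched LD or
non-normal effects enter as unmodeled error.

Causal-gene prioritization assumes **one causal gene per region**. Bayes
factors compare `z_i ~ N(0, 1 + nσ²α)` (gene i causal) against
`z_i ~ N(0, 1)`, and posteriors normalize over the genes in the region
only. Regions with several truly causal genes, or none, violate this model;
that is a documented limitation, not a configurable option.

## Quality control and harmonization

Summary statistics pass three filters: MAF ≥ 0.01 (frequency columns are
folded to min(f, 1−f)), removal of strand-ambiguous variants (A/T, C/G),
and an `rs[0-9]+` identifier check (no external database lookup). Allele
harmonization against the LD reference flips Z signs for swapped alleles
and resolves strand flips by complement-matching — safe only because
ambiguous pairs were already removed, which is why QC precedes
harmonization. Every removal is counted in a provenance log, and the
per-rule counts partition the removed records exactly.

## Heritability: spectral REML

`var(y′) = Aσ²g + Iσ²e` with `A = ZZ'/p` from standardized cis genotypes.
After residualizing covariates, the likelihood is profiled down to the
single parameter h² = σ²g/(σ²g+σ²e) via the thin SVD of Z (only min(n, p)
nonzero eigenvalues, so cost is O(np²) not O(n³)), then maximized on
[0, 1) by a grid of 41 points refined with bounded scalar minimization.
The significance of σ²g = 0 uses the 50:50 mixture of a point mass at zero
and χ²₁, the standard boundary correction. Null calibration (rejection
rate 4.8% at α = 0.05 over 500 null genes) and recovery (mean ĥ² = 0.398
at true 0.4, n = 500, p = 50, 200 replicates) are both verified in the
test suite. A failed optimizer returns the best boundary value with
`converged=False` rather than raising.

## Weight training

Four models compete: ridge-BLUP (ridge regression with the penalty chosen
by efficient leave-one-out CV over a log grid), LASSO and elastic net
(mixing 0.5; penalty path by internal fivefold CV), and `top1` (the single
best marginal eQTL SNP). Out-of-sample R² comes from an outer fivefold
split (shuffled, seeded — the whole procedure is deterministic given the
seed); its significance is a one-sided test on the correlation between
out-of-fold predictions and observations. The best model with P < 0.05 is
refit on all samples. Note the false-trainability rate of this selection
rule under a pure-noise gene is the union of four nominal 5% tests, about
15% empirically — genes surviving it should not be read as confirmed
heritable; that is the h² filter's job. Weights are per standardized
genotype throughout. Expression is inverse-normal rank-transformed using
rank/(n+1) quantiles with average ranks for ties.

## LD regularization

`V = (1−λ)·corr(X) + λI` with λ = 0.1 by default. The reference panels at
desk scale (hundreds of samples) can be rank-deficient against a locus's
SNP count; the ridge bounds the spectrum below by λ so that `w'Vw`,
`V_GE⁻¹`, and the conditional-variance diagonal are always finite. λ is
recorded on every LD matrix. The LD panel applies the same MAF ≥ 0.01
floor as the summary statistics so both live on one SNP universe.

## Permutation test

Weight values are shuffled across the model's own SNP slots (the literal
reading of permuting the eQTL weights), keeping **z** fixed and recomputing
`|z_perm|` each time; `perm_p = (1 + #exceed)/(1 + #perms)`. Sampling is
adaptive: it stops at `stop_exceed` exceedances. Stopping after E
exceedances leaves multiplicative noise of order 1/√E on the estimate, and
at E = 10 that noise is large enough to make null permutation P-values
visibly non-uniform (KS distance ≈ 0.09–0.12, for any of the standard
sequential estimators). The default is therefore **stop_exceed = 100**,
which keeps null P-values uniform within KS tolerance while still cutting
the cost of clearly non-significant genes by two orders of magnitude.
An exhaustive-enumeration oracle (all p! orders, feasible to p = 8) backs
the sampler in tests.

## Conditional analysis

Implements the least-squares projection exactly as displayed in the model:
`C = V W D⁻¹`, `V_GE = D⁻¹W'VWD⁻¹` with `D = diag(√(w'Vw))`. Genes with
|r| > 0.95 in `V_GE` are pruned before inversion (keeping the larger
|z_TWAS|), and SNPs whose residual variance falls below 10⁻⁶ are reported
as *fully explained* with conditional z = 0 instead of emitting
division-by-near-zero artifacts.

## Prior scale for Bayes factors

The prior effect variance enters only through `nσ²α`. Default: **nσ²α = 30**
(a causal gene's expected χ² ≈ 31, comfortably transcriptome-wide
significant at ~10⁵ tests), configurable per call; an empirical-Bayes
helper sets `nσ²α = max(0, mean(z²) − 1)` over significant genes. Posteriors
vary smoothly in this scalar, so exact reproduction of any particular
region's posterior requires the original prior; the calibration experiment
uses the matching generative prior, which is what makes coverage ≥ ρ a
theorem rather than luck — the test then verifies the implementation, not
the theory.

## Synthetic data: what it emulates, and what it does not

Genotypes: two latent AR(1) Gaussian haplotypes thresholded at each SNP's
MAF quantile. `rho_ld` is the **latent** autocorrelation; dosage LD is
attenuated by dichotomization (the phi-coefficient bound,
r ≤ (2/π)·asin(ρ) at MAF 0.5, lower at rarer alleles), so realized
adjacent-SNP LD at the default ρ = 0.7 is ≈ 0.45–0.5. Tests validate the
attenuated value, not the latent target. Expression: sparse causal SNPs
with the in-sample genetic variance fraction made *exactly* h² by
orthogonalizing the noise against the genetic component — convenient for
recovery tests, slightly anti-conservative about sampling noise in h².
GWAS: either an explicit cohort with marginal Wald statistics, or
Z-scores drawn from `MVN(√n·α·Vw̃, V)`; the two modes agree in
distribution (verified). Regions for calibration: predicted-expression
correlations built mechanistically as `D⁻¹W'VWD⁻¹` from random sparse
weights over simulated LD, not arbitrary correlation matrices.

Not emulated: realistic human LD maps, population structure, trans-eQTLs,
batch effects correlated with genotype, case-control ascertainment.
Passing tests show the *statistics* behave as derived under the model's
assumptions; they say nothing about robustness to those real-data
violations.

## Default study conditions

| parameter | default | why |
|---|---|---|
| LD reference n | 489 | European reference panel size used for V |
| GWAS n | 142,392 | the motivating GWAS's sample size |
| expression panel n | 500 | a well-powered panel within the 87–1264 range |
| SNPs per locus (p) | 50 | typical QC-passing cis SNP count at desk scale |
| latent rho_ld | 0.7 | moderate local LD after attenuation |
| MAF range | 0.05–0.5 | common variants, mirroring the MAF floor |
| h² of expression | 0.4 | a clearly heritable gene |
| causal SNPs per gene | 5 | sparse cis architecture |
| gene effect α | 0.0168 | n·α² ≈ 40: a strong, GWAS-detectable signal |
| genes per region (k) | 5 | multi-gene region for prioritization |
| nσ²α | 30 | see prior-scale section |

Problem sizes in the test and acceptance runs (1,000 calibration regions,
200 REML replicates, 100 end-to-end seeds, 500 permutation-calibration
genes) were chosen as the smallest sizes at which the binomial/Monte-Carlo
error bands in the assertions are meaningful.

## Numerical choices

- Bayes factors computed and combined in log space (`softmax`); finite to
  |z| well beyond 40.
- Degenerate quadratic forms (`w'Vw ≤ 10⁻⁸`) raise a named error rather
  than returning ±inf.
- Credible-set ties break lexicographically on gene id, making output
  deterministic.
- "TWAS stronger than GWAS" comparisons are strict; ties count as not
  stronger; an empty cis window yields an undefined (None) flag.
- Missing genotypes are mean-imputed per SNP before standardization.

## Known limitations

- Single-causal-gene regions only; no SNP-level fine-mapping or
  colocalization posterior.
- The REML here is the direct 1-D spectral maximization, appropriate for a
  single cis variance component; it does not generalize to multiple
  components.
- No liftover, INFO filtering, or meta-analysis; one genome build and one
  cohort are assumed.
- The permutation test permutes within the model's SNP slots; permuting
  across all cis SNPs is a different null and is not implemented.
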