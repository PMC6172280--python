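"""SNP-level GWAS statistics conditional on predicted gene expression.

With V the SNP LD matrix at a locus, W the p x G matrix of expression
weights (zero-padded to the common SNP order), and D = diag(sqrt(w_g'Vw_g)),
the SNP-expression correlations are C = V W D^-1 and the predicted-
expression correlations are V_GE = D^-1 W'V W D^-1.  The least-squares
residual association of each SNP after removing the component explained by
the genes' predicted expression is

    z_GWAS|z_TWAS = z_GWAS - C V_GE^-1 z_TWAS
    var[z_GWAS|z_TWAS] = V - C V_GE^-1 C'
    z_i = [z_GWAS - C V_GE^-1 z_TWAS]_i / sqrt(diag[V - C V_GE^-1 C']_ii)

Genes whose predicted expression is nearly collinear (|r| > threshold in
V_GE) are pruned before inversion, keeping the gene with the larger |z_TWAS|.
SNPs whose residual variance underflows are reported as fully explained with
conditional z = 0 rather than as division artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from twaskit.exceptions import DegenerateModelError, ValidationError
from twaskit.ld_reference import LDMatrix

_VAR_TOL = 1e-8
FULLY_EXPLAINED_TOL = 1e-6


def _as_matrix(V) -> np.ndarray:
    return V.V if isinstance(V, LDMatrix) else np.asarray(V, dtype=float)


@dataclass
class ConditionalResult:
    snp_ids: list[str]
    z_marginal: np.ndarray
    z_conditional: np.ndarray
    genes_conditioned: list[str]
    genes_pruned: list[str]
    residual_var_diag: np.ndarray
    fully_explained: np.ndarray  # boolean per SNP


def predicted_expression_correlations(
    W: np.ndarray,
    V,
    gene_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """SNP-expression correlations C and expression-expression correlations V_GE.

    ``W`` is p x G with one weight column per gene, already on V's SNP order
    (SNPs absent from a model carry zero weight).
    """
    Vm = _as_matrix(V)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != Vm.shape[0]:
        W = W.T
    if W.shape[0] != Vm.shape[0]:
        raise ValidationError("weight matrix does not match V's SNP dimension")
    VW = Vm @ W
    quad = np.einsum("pg,pg->g", W, VW)
    bad = np.flatnonzero(quad <= _VAR_TOL)
    if bad.size:
        names = [gene_ids[i] if gene_ids else f"gene{i}" for i in bad]
        raise DegenerateModelError(
            f"zero predicted-expression variance for: {', '.join(names)}"
        )
    Dinv = 1.0 / np.sqrt(quad)
    C = VW * Dinv[None, :]
    V_GE = (W.T @ VW) * np.outer(Dinv, Dinv)
    V_GE = (V_GE + V_GE.T) / 2.0
    np.fill_diagonal(V_GE, 1.0)
    return C, V_GE


def _prune_collinear(
    V_GE: np.ndarray, z_twas: np.ndarray, threshold: float
) -> list[int]:
    """Indices kept after greedy collinearity pruning (larger |z| wins)."""
    order = np.argsort(-np.abs(z_twas), kind="mergesort")
    kept: list[int] = []
    for i in order:
        if all(abs(V_GE[i, j]) <= threshold for j in kept):
            kept.append(int(i))
    return sorted(kept)


def conditional_zscores(
    z_gwas: np.ndarray,
    C: np.ndarray,
    V_GE: np.ndarray,
    z_twas_vec: np.ndarray,
    V,
    snp_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
    collinear_threshold: float = 0.95,
) -> ConditionalResult:
    """Conditional SNP association scores per the least-squares projection."""
    Vm = _as_matrix(V)
    z_gwas = np.asarray(z_gwas, dtype=float)
    z_twas_vec = np.atleast_1d(np.asarray(z_twas_vec, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != Vm.shape[0]:
        C = C.T
    V_GE = np.atleast_2d(np.asarray(V_GE, dtype=float))
    G = V_GE.shape[0]
    gene_ids = gene_ids or [f"gene{i}" for i in range(G)]
    snp_ids = snp_ids or [f"snp{i}" for i in range(Vm.shape[0])]

    keep = _prune_collinear(V_GE, z_twas_vec, collinear_threshold)
    pruned = [gene_ids[i] for i in range(G) if i not in keep]
    Ck = C[:, keep]
    Vk = V_GE[np.ix_(keep, keep)]
    zk = z_twas_vec[keep]
    try:
        A = np.linalg.solve(Vk, np.column_stack([zk, Ck.T]))
    except np.linalg.LinAlgError as err:
        raise DegenerateModelError(
            f"V_GE not invertible after pruning; collinear block among "
            f"{[gene_ids[i] for i in keep]}"
        ) from err
    adj = Ck @ A[:, 0]
    resid_var = np.diag(Vm - Ck @ A[:, 1:]).copy()
    if resid_var.min() < -1e-8:
        raise DegenerateModelError("residual variance matrix not PSD")
    resid_var = np.clip(resid_var, 0.0, None)
    fully = resid_var < FULLY_EXPLAINED_TOL
    z_cond = np.zeros_like(z_gwas)
    ok = ~fully
    z_cond[ok] = (z_gwas[ok] - adj[ok]) / np.sqrt(resid_var[ok])
    return ConditionalResult(
        snp_ids=list(snp_ids),
        z_marginal=z_gwas.copy(),
        z_conditional=z_cond,
        genes_conditioned=[gene_ids[i] for i in keep],
        genes_pruned=pruned,
        residual_var_diag=resid_var,
        fully_explained=fully,
    )


def condition_on_models(
    z_gwas: np.ndarray,
    models,
    V: LDMatrix,
    z_twas_vec: np.ndarray,
    **kwargs,
) -> ConditionalResult:
    """Convenience wrapper: build W from GeneModels aligned to V, then condition."""
    pos = {s: i for i, s in enumerate(V.snp_ids)}
    W = np.zeros((len(V.snp_ids), len(models)))
    for g, m in enumerate(models):
        for j, sid in enumerate(m.snps["snp"]):
            if sid in pos:
                W[pos[sid], g] = m.weights[j]
    gene_ids = [m.gene for m in models]
    C, V_GE = predicted_expression_correlations(W, V, gene_ids=gene_ids)
    return conditional_zscores(
        z_gwas, C, V_GE, z_twas_vec, V,
        snp_ids=V.snp_ids, gene_ids=gene_ids, **kwargs,
    )
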