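"""Expression normalization, cis-heritability, and predictive weight models.

The expression model for a gene is y_GE = C beta + X w_GE + eps: covariates,
a linear function of cis-SNP genotypes, and environmental noise.  This module

- rank-transforms expression to normality,
- estimates cis-SNP heritability h2g under the variance-component model
  var(y') = A sigma_g^2 + I sigma_e^2 (A = ZZ'/p the local kinship matrix),
  by direct 1-D restricted-likelihood maximization over h2 after a spectral
  decomposition, with a likelihood-ratio P-value against sigma_g^2 = 0 using
  the 50:50 chi2_0/chi2_1 boundary mixture,
- filters genes whose h2g is not nominally significant, and
- trains a menu of penalized predictors (ridge-BLUP, LASSO, elastic net, and
  the single best marginal eQTL) with fivefold out-of-sample R^2, keeping the
  best model whose R^2 is nominally non-zero (P < 0.05).

Weights are per *standardized* genotype throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri
from sklearn.linear_model import ElasticNetCV, LassoCV, RidgeCV
from sklearn.model_selection import KFold

from twaskit.exceptions import ValidationError
from twaskit.ld_reference import GenotypeMatrix

MODEL_MENU = ("blup", "lasso", "enet", "top1")


@dataclass
class H2Estimate:
    """cis-SNP heritability of one gene with its variance components."""

    h2: float
    sigma_g2: float
    sigma_e2: float
    p_value: float
    converged: bool


@dataclass
class GeneModel:
    """Trained predictive weights for one gene x panel."""

    gene: str
    panel: str
    snps: pd.DataFrame  # columns: snp, a1, a2
    weights: np.ndarray  # per standardized genotype
    model_label: str
    cv_r2: float
    cv_p: float
    h2: H2Estimate | None = None


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with a rank/(n+1) quantile offset.

    Ties receive average ranks.  Monotone transforms of the input yield
    identical output; reversing the input negates it.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValidationError("need at least 3 values to rank-normalize")
    if np.all(values == values[0]):
        raise ValidationError("all values tied; rank transform undefined")
    ranks = stats.rankdata(values, method="average")
    return ndtri(ranks / (n + 1))


def residualize(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Remove fixed-effect covariates (plus intercept) by least squares."""
    y = np.asarray(y, dtype=float)
    design = np.ones((y.size, 1))
    if C is not None and np.asarray(C).size:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        design = np.hstack([design, C])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _standardize_genotypes(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.standardized()
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError(f"constant genotype column at index {int(np.argmax(sd == 0))}")
    return Z / sd


def estimate_cis_h2(
    y: np.ndarray,
    X,
    C: np.ndarray | None = None,
    h2_max: float = 1.0 - 1e-6,
) -> H2Estimate:
    """Spectral REML for h2 = sigma_g2 / (sigma_g2 + sigma_e2) on one gene.

    Residualizes covariates from y, forms A = ZZ'/p from standardized
    genotypes, and maximizes the profile log-likelihood of
    y' ~ N(0, s2 [h2 A + (1 - h2) I]) over h2 in [0, 1] using the thin SVD
    of Z (so only min(n, p) eigenvalues are needed).  The P-value tests
    sigma_g2 = 0 by LRT under the half-point-mass, half-chi2(1) mixture.
    """
    Z = _standardize_genotypes(X)
    n, p = Z.shape
    yr = residualize(y, C)

    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    d = s**2 / p  # nonzero eigenvalues of A, padded with zeros to n
    u2 = (U.T @ yr) ** 2
    total = float(yr @ yr)
    rss0 = max(total - float(u2.sum()), 0.0)  # mass in the null space of A
    n0 = n - d.size

    def negloglik(h2: float) -> float:
        lam = h2 * d + (1.0 - h2)
        lam0 = 1.0 - h2
        q = float((u2 / lam).sum()) + (rss0 / lam0 if n0 > 0 else 0.0)
        logdet = float(np.log(lam).sum()) + (n0 * np.log(lam0) if n0 > 0 else 0.0)
        return 0.5 * (n * np.log(q / n) + logdet)

    grid = np.linspace(0.0, h2_max, 41)
    vals = [negloglik(h) for h in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    converged = True
    if hi > lo:
        res = optimize.minimize_scalar(
            negloglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        converged = bool(res.success)
        h2_hat = float(res.x) if res.success and res.fun <= vals[i] else float(grid[i])
    else:
        h2_hat = float(grid[i])

    nll_hat = negloglik(h2_hat)
    lam = h2_hat * d + (1.0 - h2_hat)
    q = float((u2 / lam).sum()) + (rss0 / (1.0 - h2_hat) if n0 > 0 else 0.0)
    s2 = q / n
    lrt = 2.0 * (negloglik(0.0) - nll_hat)
    p_value = 1.0 if lrt <= 0 else float(0.5 * stats.chi2.sf(lrt, df=1))
    p_value = min(max(p_value, np.finfo(float).tiny), 1.0)
    return H2Estimate(
        h2=h2_hat,
        sigma_g2=s2 * h2_hat,
        sigma_e2=s2 * (1.0 - h2_hat),
        p_value=p_value,
        converged=converged,
    )


def filter_heritable(
    estimates: dict[str, H2Estimate],
    alpha: float = 0.05,
) -> list[str]:
    """Genes whose cis-h2g is nominally significant (strict P < alpha)."""
    return [g for g, est in estimates.items() if est.p_value < alpha]


def _fit_model(label: str, Z, y, seed: int):
    """Return a fitted weight vector for one model on (Z, y)."""
    if label == "top1":
        score = Z.T @ y
        j = int(np.argmax(np.abs(score)))
        w = np.zeros(Z.shape[1])
        w[j] = score[j] / Z.shape[0]  # marginal OLS beta on standardized dosage
        return w
    if label == "blup":
        est = RidgeCV(alphas=np.logspace(-2, 6, 17), fit_intercept=False)
    elif label == "lasso":
        est = LassoCV(cv=5, fit_intercept=False, random_state=seed, alphas=50)
    elif label == "enet":
        est = ElasticNetCV(
            l1_ratio=0.5, cv=5, fit_intercept=False, random_state=seed, alphas=50
        )
    else:
        raise ValidationError(f"unknown model label '{label}'")
    est.fit(Z, y)
    return est.coef_.copy()


def _oos_r2(yhat: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Out-of-sample R^2 (1 - SSres/SStot) and one-sided correlation P."""
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - yhat) ** 2).sum()) / sstot
    if np.std(yhat) == 0 or np.std(y) == 0:
        return r2, 1.0
    r = float(np.corrcoef(yhat, y)[0, 1])
    n = y.size
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(stats.t.sf(t, df=n - 2))  # one-sided: prediction positively tracks truth
    return r2, p


def train_weights(
    y: np.ndarray,
    X,
    C: np.ndarray | None = None,
    folds: int = 5,
    models: tuple[str, ...] = MODEL_MENU,
    seed: int = 0,
    gene: str = "gene",
    panel: str = "panel",
    h2: H2Estimate | None = None,
    alpha: float = 0.05,
) -> GeneModel | None:
    """Train the model menu, select by cross-validated R^2, refit on all data.

    Returns None when no model achieves nominally significant out-of-sample
    accuracy (the gene is untrainable and excluded downstream).  Fold
    assignment, and hence the whole procedure, is deterministic given
    ``seed``.
    """
    Z = _standardize_genotypes(X)
    yr = residualize(y, C)
    n = yr.size
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)

    results = []
    for label in models:
        yhat = np.empty(n)
        for train, test in kf.split(Z):
            w = _fit_model(label, Z[train], yr[train], seed)
            yhat[test] = Z[test] @ w
        r2, p = _oos_r2(yhat, yr)
        results.append((label, r2, p))

    snps = (
        X.snps[["snp", "a1", "a2"]].copy()
        if isinstance(X, GenotypeMatrix)
        else pd.DataFrame(
            {"snp": [f"snp{j}" for j in range(Z.shape[1])], "a1": "A", "a2": "G"}
        )
    )
    for label, r2, p in sorted(results, key=lambda t: -t[1]):
        if p >= alpha:
            continue
        w = _fit_model(label, Z, yr, seed)
        if not np.any(w != 0):
            continue  # penalty zeroed every weight on the full refit
        return GeneModel(
            gene=gene, panel=panel, snps=snps, weights=w,
            model_label=label, cv_r2=r2, cv_p=p, h2=h2,
        )
    return None


def normalized_accuracy(cv_r2: float, h2: float) -> float:
    """Prediction accuracy relative to its heritability ceiling: min(R2/h2, 1).

    Negative out-of-sample R^2 clamps to 0.  h2 must be positive.
    """
    if h2 <= 0:
        raise ValidationError(f"normalized accuracy undefined for h2 = {h2}")
    return min(max(cv_r2, 0.0) / h2, 1.0)


def save_weights(model: GeneModel, path) -> None:
    out = model.snps.copy()
    out["weight"] = model.weights
    out.to_csv(path, sep="\t", index=False)


def load_weights(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp": str, "a1": str, "a2": str})
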