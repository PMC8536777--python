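"""Empirical-Bayes location-scale batch adjustment across sampling series.

The model and estimators follow the classical parametric empirical-Bayes
batch-adjustment scheme: per-gene standardization against a covariate fit,
per-(gene, batch) location (gamma) and scale (delta^2) estimates, normal and
inverse-gamma priors with method-of-moments hyperparameters, and an
iterative shrinkage solution.  Biological covariates (condition, time) can
be protected so their signal survives adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts_io import NormalizedMatrix


@dataclass
class BatchModel:
    batches: list
    gamma_hat: np.ndarray   # batch x gene raw location estimates
    delta2_hat: np.ndarray  # batch x gene raw scale estimates
    gamma_star: np.ndarray  # EB-shrunken
    delta2_star: np.ndarray
    gamma_bar: np.ndarray   # prior mean of gamma, per batch
    tau2_bar: np.ndarray    # prior variance of gamma, per batch
    a_prior: np.ndarray     # inverse-gamma shape, per batch
    b_prior: np.ndarray     # inverse-gamma scale, per batch
    grand_mean: np.ndarray  # per gene (alpha + batch-size-weighted gamma)
    pooled_sd: np.ndarray   # per gene
    beta_cov: np.ndarray    # covariate coefficients (p x gene), may be empty
    batch_sizes: dict = field(default_factory=dict)
    n_iter: int = 0

    def to_json(self, path) -> None:
        payload = {
            "batches": [str(b) for b in self.batches],
            "batch_sizes": {str(k): int(v) for k, v in self.batch_sizes.items()},
            "gamma_bar": self.gamma_bar.tolist(),
            "tau2_bar": self.tau2_bar.tolist(),
            "a_prior": self.a_prior.tolist(),
            "b_prior": self.b_prior.tolist(),
            "n_iter": self.n_iter,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _postmean(gamma_hat, gamma_bar, n, delta2_star, tau2_bar):
    return (tau2_bar * n * gamma_hat + delta2_star * gamma_bar) / (tau2_bar * n + delta2_star)


def moments_prior_gamma(gamma_hat_b: np.ndarray) -> tuple[float, float]:
    """Method-of-moments normal prior for a batch's gamma vector."""
    return float(gamma_hat_b.mean()), float(gamma_hat_b.var(ddof=1))


def moments_prior_delta2(delta2_hat_b: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma prior (shape a, scale b)."""
    m = float(delta2_hat_b.mean())
    s2 = float(delta2_hat_b.var(ddof=1))
    a = (2.0 * s2 + m * m) / s2
    b = (m * s2 + m ** 3) / s2
    return a, b


def fit_batch_model(matrix: NormalizedMatrix, batch_labels,
                    covariates: pd.DataFrame | np.ndarray | None = None,
                    tol: float = 1e-4, max_iter: int = 100) -> BatchModel:
    """Fit the EB batch model on a normalized genes x samples matrix.

    ``covariates`` (samples x p, no intercept) protects biological signal:
    it is included in the standardization fit and restored on adjustment.
    """
    X = matrix.values.to_numpy().astype(float)
    n_genes, n_samples = X.shape
    batch_labels = np.asarray([str(b) for b in batch_labels])
    if len(batch_labels) != n_samples:
        raise ValueError("batch_labels length must match sample count")
    batches = sorted(set(batch_labels))
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    sizes = {b: int((batch_labels == b).sum()) for b in batches}
    for b, n in sizes.items():
        if n < 2:
            raise ValueError(f"batch {b!r} has {n} sample(s); need >= 2")

    B = np.column_stack([(batch_labels == b).astype(float) for b in batches])
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        design = np.column_stack([B, C])
    else:
        C = np.empty((n_samples, 0))
        design = B
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is singular (collinear batch/covariates)")

    # per-gene OLS on [batch dummies | covariates]
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (nbatch+p) x gene
    gamma_full = coef[:len(batches)]
    beta_cov = coef[len(batches):]
    weights = np.array([sizes[b] for b in batches], dtype=float) / n_samples
    grand_mean = weights @ gamma_full  # per gene

    fitted = design @ coef
    resid = X.T - fitted
    pooled_var = (resid ** 2).mean(axis=0)
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))

    stand_mean = grand_mean[None, :] + C @ beta_cov  # samples x genes
    Z = (X.T - stand_mean) / pooled_sd[None, :]      # samples x genes

    nb = len(batches)
    gamma_hat = np.zeros((nb, n_genes))
    delta2_hat = np.zeros((nb, n_genes))
    for i, b in enumerate(batches):
        rows = batch_labels == b
        gamma_hat[i] = Z[rows].mean(axis=0)
        delta2_hat[i] = Z[rows].var(axis=0, ddof=1)
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    gamma_bar = np.zeros(nb)
    tau2_bar = np.zeros(nb)
    a_prior = np.zeros(nb)
    b_prior = np.zeros(nb)
    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter_total = 0
    for i, b in enumerate(batches):
        gamma_bar[i], tau2_bar[i] = moments_prior_gamma(gamma_hat[i])
        a_prior[i], b_prior[i] = moments_prior_delta2(delta2_hat[i])
        rows = batch_labels == b
        n_b = sizes[b]
        Zb = Z[rows]
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        for it in range(max_iter):
            g_new = _postmean(gamma_hat[i], gamma_bar[i], n_b, d_old, tau2_bar[i])
            ssq = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (b_prior[i] + 0.5 * ssq) / (n_b / 2.0 + a_prior[i] - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            change = max(np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
                         np.abs(d_new - d_old).max() / d_old.max())
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        n_iter_total = max(n_iter_total, it + 1)
        gamma_star[i] = g_old
        delta2_star[i] = d_old

    return BatchModel(batches=batches, gamma_hat=gamma_hat, delta2_hat=delta2_hat,
                      gamma_star=gamma_star, delta2_star=delta2_star,
                      gamma_bar=gamma_bar, tau2_bar=tau2_bar,
                      a_prior=a_prior, b_prior=b_prior,
                      grand_mean=grand_mean, pooled_sd=pooled_sd,
                      beta_cov=beta_cov, batch_sizes=sizes, n_iter=n_iter_total)


def adjust(matrix: NormalizedMatrix, model: BatchModel, batch_labels,
           covariates: pd.DataFrame | np.ndarray | None = None) -> NormalizedMatrix:
    """Remove the shrunken batch effects and restore gene-level scale.

    Single-batch input (no model applicable) returns the input unchanged.
    """
    X = matrix.values.to_numpy().astype(float)
    batch_labels = np.asarray([str(b) for b in batch_labels])
    present = sorted(set(batch_labels))
    if len(present) < 2:
        return NormalizedMatrix(values=matrix.values.copy(), method=matrix.method,
                                params={**matrix.params, "batch_adjusted": False})
    unseen = set(present) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch labels: {sorted(unseen)}")

    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    else:
        C = np.empty((X.shape[1], 0))
    stand_mean = model.grand_mean[None, :] + C @ model.beta_cov
    Z = (X.T - stand_mean) / model.pooled_sd[None, :]
    out = Z.copy()
    for i, b in enumerate(model.batches):
        rows = batch_labels == b
        if not rows.any():
            continue
        out[rows] = (Z[rows] - model.gamma_star[i][None, :]) / np.sqrt(model.delta2_star[i])[None, :]
    adjusted = (out * model.pooled_sd[None, :] + stand_mean).T
    vals = pd.DataFrame(adjusted, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizedMatrix(values=vals, method=matrix.method,
                            params={**matrix.params, "batch_adjusted": True})
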