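"""Sparse CpG risk signature by stacked generalisation.

Many elastic-net logistic base classifiers (default 100, mixing
alpha = 0.1) are trained on the candidate CpGs, each with its own
cross-validation fold partition choosing the penalty strength at
minimum cross-validated deviance.  A meta learner then fits a
non-negative-weight logistic combination of the base classifiers'
out-of-fold linear predictors.  Because every base score is linear in
the (standardized) beta values, the stacked model collapses to a single
sparse coefficient vector — the risk signature — as the weighted sum of
the base coefficient vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit
from sklearn.model_selection import StratifiedKFold

from ._enet import binomial_deviance, enet_logistic_path, lambda_grid
from .diffmeth import CandidateSet
from .methio import BetaMatrix, Signature

__all__ = [
    "EnsembleConfig",
    "ElasticNetFit",
    "cv_elastic_net",
    "stack_ensemble",
    "signature_summary",
]


@dataclass
class EnsembleConfig:
    """Knobs of the stacked elastic-net derivation.

    ``alpha`` is the L1/L2 mixing (0.1 leans towards ridge, keeping
    groups of correlated CpGs together); ``n_base`` the number of base
    classifiers combined by stacking; the penalty grid is log-spaced
    from a data-driven maximum down by ``lambda_min_ratio``.
    """

    alpha: float = 0.1
    n_base: int = 100
    n_folds: int = 10
    n_lambda: int = 30
    lambda_min_ratio: float = 0.01
    meta_rule: str = "nonneg_stack"  # or "mean"
    tol: float = 1e-4
    use_all_cpgs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_base < 1:
            raise ValueError("n_base must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.meta_rule not in ("nonneg_stack", "mean"):
            raise ValueError("meta_rule must be 'nonneg_stack' or 'mean'")


@dataclass
class ElasticNetFit:
    """One cross-validated base classifier.

    ``oof_eta`` holds the out-of-fold linear predictor of every training
    sample (each sample predicted exactly once, by the fold that held it
    out) at the selected penalty.
    """

    coefficients: np.ndarray
    intercept: float
    lambda_selected: float
    oof_eta: np.ndarray
    lambdas: np.ndarray
    cv_deviance: np.ndarray

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.coefficients))


def cv_elastic_net(X: np.ndarray, y: np.ndarray, config: EnsembleConfig,
                   fold_seed: int) -> ElasticNetFit:
    """Elastic-net logistic fit with penalty chosen by stratified CV.

    ``X`` must be a standardized (and imputed) samples x features
    matrix.  The penalty grid is shared across folds; lambda minimizing
    the summed out-of-fold binomial deviance wins (ties favour the
    larger, sparser penalty), and the model is refit on all data at that
    lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < config.n_folds:
        raise ValueError(f"fewer samples ({n}) than folds ({config.n_folds})")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before fitting")
    prev = y.mean()
    if not np.ptp(X, axis=0).any():
        warnings.warn("all features constant; returning all-zero fit",
                      RuntimeWarning)
        b0 = float(logit(prev)) if 0 < prev < 1 else 0.0
        lam = 1.0
        return ElasticNetFit(np.zeros(p), b0, lam, np.full(n, b0),
                             np.array([lam]), np.array([np.nan]))

    lambdas = lambda_grid(X, y, config.alpha, config.n_lambda,
                          config.lambda_min_ratio)
    L = lambdas.size
    oof = np.empty((n, L))
    deviance = np.zeros(L)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=int(fold_seed) % (2**32 - 1))
    for train, test in skf.split(X, y):
        b0s, coefs = enet_logistic_path(X[train], y[train], config.alpha,
                                        lambdas, tol=config.tol)
        eta_test = X[test] @ coefs.T + b0s[None, :]
        oof[test] = eta_test
        for li in range(L):
            deviance[li] += binomial_deviance(y[test], eta_test[:, li])
    best = int(np.argmin(deviance))
    b0s, coefs = enet_logistic_path(X, y, config.alpha, lambdas,
                                    tol=config.tol)
    return ElasticNetFit(
        coefficients=coefs[best],
        intercept=float(b0s[best]),
        lambda_selected=float(lambdas[best]),
        oof_eta=oof[:, best],
        lambdas=lambdas,
        cv_deviance=deviance,
    )


def _meta_weights(Z: np.ndarray, y: np.ndarray, rule: str) -> tuple[np.ndarray, float]:
    """Combine base out-of-fold predictors: non-negative logistic
    stacking (weights >= 0, free intercept) or a plain mean."""
    n, k = Z.shape
    if rule == "mean":
        return np.full(k, 1.0 / k), 0.0

    def nll_grad(x):
        w, c = x[:k], x[k]
        eta = Z @ w + c
        mu = 1.0 / (1.0 + np.exp(-eta))
        nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta)) / n
        g_eta = (mu - y) / n
        return nll, np.concatenate([Z.T @ g_eta, [g_eta.sum()]])

    x0 = np.concatenate([np.full(k, 1.0 / k), [0.0]])
    bounds = [(0.0, None)] * k + [(None, None)]
    res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500})
    return res.x[:k], float(res.x[k])


def stack_ensemble(matrix: BetaMatrix, y, config: EnsembleConfig,
                   candidates: CandidateSet | None = None) -> Signature:
    """Derive the stacked elastic-net risk signature.

    ``matrix`` is the discovery beta matrix; ``y`` the binary group
    labels aligned with its samples; ``candidates`` restricts the
    feature universe to an FDR-selected CpG set (the default when
    supplied; ``config.use_all_cpgs`` overrides).  Fold partitions of
    the ``n_base`` base classifiers differ by sub-seeds derived
    deterministically from ``config.seed``.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != matrix.shape[1]:
        raise ValueError("labels do not match the matrix samples")
    if y.shape[0] < 20:
        raise ValueError("need at least 20 samples to derive a signature")
    if candidates is not None and not config.use_all_cpgs:
        sub = matrix.subset_cpgs(candidates.cpg_ids)
    else:
        sub = matrix
    cpg_ids = sub.cpg_ids
    if len(cpg_ids) == 0:
        raise ValueError("empty CpG universe: candidate set shares no CpGs "
                         "with the matrix")
    X = sub.values.to_numpy(dtype=float).T  # samples x cpgs

    # impute per-CpG means, then standardize; constant CpGs get scale 1
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, col_mean[None, :], X)
    scales = X.std(axis=0, ddof=0)
    scales[scales == 0.0] = 1.0
    Xs = (X - col_mean[None, :]) / scales[None, :]

    sub_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_base)
    base_fits = [cv_elastic_net(Xs, y, config, int(s)) for s in sub_seeds]
    base_coefs = np.array([f.coefficients for f in base_fits])
    if not np.any(base_coefs):
        raise RuntimeError("no signal retained: every base fit is all-zero")
    Z = np.column_stack([f.oof_eta for f in base_fits])
    w, _meta_intercept = _meta_weights(Z, y, config.meta_rule)
    combined = base_coefs.T @ w
    nonzero = combined != 0.0
    if not nonzero.any():
        raise RuntimeError("no signal retained: meta weights zeroed all CpGs")

    idx = cpg_ids[nonzero]
    metadata = {
        "alpha": config.alpha,
        "n_base": config.n_base,
        "n_folds": config.n_folds,
        "n_lambda": config.n_lambda,
        "lambda_min_ratio": config.lambda_min_ratio,
        "meta_rule": config.meta_rule,
        "seed": config.seed,
        "coefficient_scale": "standardized_beta",
    }
    if candidates is not None and not config.use_all_cpgs:
        metadata["fdr_threshold"] = candidates.fdr_threshold
    return Signature(
        coefficients=pd.Series(combined[nonzero], index=idx),
        means=pd.Series(col_mean[nonzero], index=idx),
        scales=pd.Series(scales[nonzero], index=idx),
        metadata=metadata,
    )


def signature_summary(sig: Signature) -> tuple[int, int, int]:
    """(n_total, n_hyper, n_hypo): positive coefficients mark CpGs whose
    higher methylation raises the risk score (hypermethylated in
    carriers), negative ones the reverse."""
    if len(sig) == 0:
        raise ValueError("empty signature")
    n_hyper = int((sig.coefficients > 0).sum())
    n_hypo = int((sig.coefficients < 0).sum())
    return n_hyper + n_hypo, n_hyper, n_hypo
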