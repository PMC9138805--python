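"""Parametric empirical-Bayes batch adjustment (ComBat-style).

Each feature is standardized under a linear model containing batch
indicators plus preserved covariates (group, sex, ...); per-batch location
and scale estimates are then shrunk across features with the standard
parametric empirical-Bayes priors (normal prior on locations, inverse-gamma
on scales, both moment-matched) and removed. The biological covariate
effects are put back, so a preserved group contrast survives adjustment.

``ComBatAdjuster`` follows the scikit-learn estimator protocol
(``get_params``/``set_params``, fitted attributes with trailing
underscores); like its R namesake it adjusts the batch structure it was
fitted on, so ``fit_transform`` is the natural entry point.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ComBatAdjuster"]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_solve(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterate the coupled location/scale posterior equations to a fixpoint."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(5000):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max()
            if np.abs(g_old).max() > 0 else 0.0,
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class ComBatAdjuster(TransformerMixin, BaseEstimator):
    """Remove additive and multiplicative batch effects per feature.

    Parameters
    ----------
    parametric : bool
        Use the parametric empirical-Bayes priors (the only implemented
        variant; kept as a parameter for interface clarity).
    shrink : bool
        When False, skip the empirical-Bayes shrinkage and remove the raw
        per-batch location/scale estimates (useful for tests and for very
        large feature sets where shrinkage is negligible).

    Attributes
    ----------
    gamma_star_ : ndarray of shape (n_batches, n_features)
        Shrunk batch location effects on the standardized scale.
    delta_star_ : ndarray of shape (n_batches, n_features)
        Shrunk batch scale effects.
    batch_levels_ : ndarray
        Batch labels in the order of the effect rows.
    """

    def __init__(self, parametric: bool = True, shrink: bool = True,
                 conv: float = 1e-4):
        self.parametric = parametric
        self.shrink = shrink
        self.conv = conv

    def fit(self, X, y=None, *, batch, covariates=None):
        """Estimate batch effects.

        Parameters
        ----------
        X : array-like of shape (n_samples, n_features)
        batch : array-like of shape (n_samples,)
            Batch label per sample; >= 2 batches with >= 2 samples each.
        covariates : array-like of shape (n_samples, n_covariates), optional
            Biological covariates to preserve (e.g. group, sex), numeric
            or one-hot encoded. Must not be confounded with batch.
        """
        if not self.parametric:
            raise NotImplementedError("only the parametric variant is implemented")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if batch.shape[0] != X.shape[0]:
            raise ValueError("batch must have one label per sample")
        levels, batch_idx = np.unique(batch, return_inverse=True)
        if levels.size < 2:
            raise ValueError("need >= 2 batches")
        counts = np.bincount(batch_idx)
        if counts.min() < 2:
            raise ValueError("every batch needs >= 2 samples")
        n, p = X.shape
        batch_design = np.eye(levels.size)[batch_idx]
        design = batch_design
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cov = cov - cov.mean(axis=0)  # centre so batch columns absorb means
            design = np.hstack([batch_design, cov])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(
                "design is rank deficient: batch is confounded with a covariate"
            )
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        grand_mean = (counts / n) @ beta[: levels.size]
        resid = X - design @ beta
        var_pooled = (resid**2).mean(axis=0)
        if np.any(var_pooled == 0):
            raise ValueError("zero-variance feature; drop constant features first")
        stand_mean = np.tile(grand_mean, (n, 1))
        if covariates is not None:
            stand_mean = stand_mean + design[:, levels.size:] @ beta[levels.size:]
        z = (X - stand_mean) / np.sqrt(var_pooled)

        gamma_hat = np.vstack([z[batch_idx == i].mean(axis=0)
                               for i in range(levels.size)])
        delta_hat = np.vstack([z[batch_idx == i].var(axis=0, ddof=1)
                               for i in range(levels.size)])
        if self.shrink:
            gamma_star = np.empty_like(gamma_hat)
            delta_star = np.empty_like(delta_hat)
            for i in range(levels.size):
                g_bar = gamma_hat[i].mean()
                t2 = gamma_hat[i].var(ddof=1)
                a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
                gamma_star[i], delta_star[i] = _it_solve(
                    z[batch_idx == i], gamma_hat[i], delta_hat[i],
                    g_bar, t2, a, b, self.conv,
                )
        else:
            gamma_star, delta_star = gamma_hat, delta_hat

        self.batch_levels_ = levels
        self.batch_idx_ = batch_idx
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.var_pooled_ = var_pooled
        self.stand_mean_ = stand_mean
        self.n_features_in_ = p
        self._z = z
        return self

    def transform(self, X=None):
        """Return the batch-adjusted matrix for the data seen at fit time.

        ``X`` is accepted for pipeline compatibility and must equal the
        fitted data's shape; the adjustment itself uses the fitted batch
        structure (ComBat semantics).
        """
        z_adj = self._z.copy()
        for i in range(self.batch_levels_.size):
            rows = self.batch_idx_ == i
            z_adj[rows] = (
                (z_adj[rows] - self.gamma_star_[i]) / np.sqrt(self.delta_star_[i])
            )
        return z_adj * np.sqrt(self.var_pooled_) + self.stand_mean_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
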