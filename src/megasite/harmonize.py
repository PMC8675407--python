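"""Batch-effect harmonization: ComBat empirical Bayes and a random-intercept
regression alternative.

ComBat models each measurement as

    Y_jv = alpha_v + X_j beta_v + gamma_iv + delta_iv * eps_jv,

with an additive (location, gamma) and a multiplicative (scale, delta) effect
per batch i (site/scanner) and element v.  Per-batch effects estimated on
standardized residuals are shrunk across elements via parametric empirical
Bayes — a normal prior on gamma and an inverse-gamma prior on delta^2, with
hyperparameters set by the method of moments — and then removed, while
covariate effects of interest or known nuisance (age, sex, ...) are retained:

    Y*_jv = sigma_v * (Z_jv - gamma*_iv) / delta*_iv + alpha_v + X_j beta_v.

The random-intercept alternative removes only a shrunken per-site intercept
(location, no scale), with the shrinkage factor derived from one-way
between/within variance components; the two routes give closely similar
group-effect estimates when batch effects are location-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, EstimationError


def _as_matrix(Y) -> np.ndarray:
    from .simdata import MeasureMatrix

    if isinstance(Y, MeasureMatrix):
        return Y.to_array()
    return np.asarray(Y, dtype=float)


def _batch_onehot(batch) -> tuple[np.ndarray, list, np.ndarray]:
    batch = np.asarray(batch)
    levels, inverse = np.unique(batch, return_inverse=True)
    onehot = np.zeros((len(batch), len(levels)))
    onehot[np.arange(len(batch)), inverse] = 1.0
    return onehot, list(levels), inverse


@dataclass
class CombatParams:
    """Fitted ComBat model: standardization fit plus EB-shrunk batch effects."""

    alpha: np.ndarray          # (V,) grand intercept per element
    beta: np.ndarray           # (p, V) retained covariate effects
    pooled_var: np.ndarray     # (V,) pooled residual variance
    gamma_star: np.ndarray     # (B, V) shrunk additive batch effects (std scale)
    delta_star_sq: np.ndarray  # (B, V) shrunk multiplicative effects (variance)
    gamma_bar: np.ndarray      # (B,) prior means
    tau_sq: np.ndarray         # (B,) prior variances
    lambda_: np.ndarray        # (B,) inverse-gamma shape hyperparameters
    theta: np.ndarray          # (B,) inverse-gamma scale hyperparameters
    batch_levels: list
    covariate_names: list
    n_batches: np.ndarray      # (B,) batch sizes at fit time
    converged: bool = True

    @property
    def delta_star(self) -> np.ndarray:
        return np.sqrt(self.delta_star_sq)


def _check_design(onehot: np.ndarray, X: np.ndarray | None, n_batch: int):
    if X is None or X.size == 0:
        return None
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError("covariate design X_keep is rank deficient")
    full = np.hstack([onehot, X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ConfigurationError(
            "covariates are confounded with batch (aliased columns); "
            "remove batch-indicator-like columns from X_keep"
        )
    return X


def combat_fit(
    Y,
    batch,
    X_keep: np.ndarray | None = None,
    covariate_names: list | None = None,
    eb: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> CombatParams:
    """Estimate ComBat location/scale batch parameters with EB shrinkage.

    ``eb=False`` switches off shrinkage (infinite-variance priors), in which
    case the location step reduces exactly to per-batch mean-centering of the
    standardized residuals.
    """
    Y = _as_matrix(Y)
    N, V = Y.shape
    onehot, levels, inverse = _batch_onehot(batch)
    B = len(levels)
    if B < 2:
        raise ConfigurationError("nothing to harmonize: need at least 2 batches")
    n_b = onehot.sum(axis=0)
    if np.any(n_b < 2):
        small = [levels[i] for i in np.where(n_b < 2)[0]]
        raise EstimationError(f"batches with a single subject: {small}")
    X = _check_design(onehot, X_keep, B)

    design = onehot if X is None else np.hstack([onehot, X])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    batch_coef = coef[:B]            # (B, V) per-batch intercepts
    beta = coef[B:]                  # (p, V)
    alpha = (n_b / N) @ batch_coef   # weighted-mean-zero constraint on gamma
    fitted = design @ coef
    pooled_var = ((Y - fitted) ** 2).sum(axis=0) / N
    if np.any(pooled_var <= 0):
        raise EstimationError("zero pooled variance at some elements")
    sigma = np.sqrt(pooled_var)

    stand_mean = alpha[None, :] + (0 if X is None else X @ beta)
    Z = (Y - stand_mean) / sigma[None, :]

    gamma_hat = (onehot.T @ Z) / n_b[:, None]                     # (B, V)
    delta_hat_sq = np.empty((B, V))
    for i in range(B):
        delta_hat_sq[i] = Z[inverse == i].var(axis=0, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat_sq.mean(axis=1)
    s2 = delta_hat_sq.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lambda_ = (2.0 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2

    if not eb:
        gamma_star, delta_star_sq = gamma_hat, delta_hat_sq
        converged = True
    else:
        gamma_star = gamma_hat.copy()
        delta_star_sq = delta_hat_sq.copy()
        converged = True
        for i in range(B):
            g_old = gamma_hat[i].copy()
            d_old = delta_hat_sq[i].copy()
            Zi = Z[inverse == i]
            ok = False
            for _ in range(max_iter):
                g_new = (n_b[i] * tau_sq[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                    n_b[i] * tau_sq[i] + d_old
                )
                sum2 = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (theta[i] + 0.5 * sum2) / (n_b[i] / 2.0 + lambda_[i] - 1.0)
                change = max(
                    np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max()
                )
                g_old, d_old = g_new, d_new
                if change < tol:
                    ok = True
                    break
            if not ok:
                warnings.warn(
                    f"ComBat EB iteration did not converge for batch {levels[i]!r}; "
                    "using the last iterate"
                )
            gamma_star[i], delta_star_sq[i] = g_old, d_old
            converged = converged and ok

    return CombatParams(
        alpha=alpha, beta=beta, pooled_var=pooled_var,
        gamma_star=gamma_star, delta_star_sq=delta_star_sq,
        gamma_bar=gamma_bar, tau_sq=tau_sq, lambda_=lambda_, theta=theta,
        batch_levels=levels,
        covariate_names=list(covariate_names or []),
        n_batches=n_b, converged=converged,
    )


def combat_apply(Y, params: CombatParams, batch, X_keep: np.ndarray | None = None):
    """Remove the fitted batch effects while restoring covariate effects."""
    Y = _as_matrix(Y)
    batch = np.asarray(batch)
    level_index = {lv: i for i, lv in enumerate(params.batch_levels)}
    unseen = sorted({str(b) for b in batch if b not in level_index})
    if unseen:
        raise DataError(f"batch labels not seen at fit time: {unseen}")
    idx = np.array([level_index[b] for b in batch])
    X = None
    if X_keep is not None and np.asarray(X_keep).size:
        X = np.asarray(X_keep, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != params.beta.shape[0]:
            raise DataError("X_keep column count differs from the fitted design")
    sigma = np.sqrt(params.pooled_var)
    stand_mean = params.alpha[None, :] + (0 if X is None else X @ params.beta)
    Z = (Y - stand_mean) / sigma[None, :]
    Z_adj = (Z - params.gamma_star[idx]) / np.sqrt(params.delta_star_sq[idx])
    return Z_adj * sigma[None, :] + stand_mean


def combat(Y, batch, X_keep: np.ndarray | None = None, **kwargs):
    """Convenience fit-then-apply on the same data; returns (Y*, params)."""
    params = combat_fit(Y, batch, X_keep, **kwargs)
    return combat_apply(Y, params, batch, X_keep), params


def random_intercept_adjust(Y, site, X_keep: np.ndarray | None = None) -> np.ndarray:
    """Location-only alternative: subtract shrunken per-site intercepts.

    Per element, residuals after removing an intercept and X_keep are averaged
    per site; the site means are shrunk by lambda_i = s_b^2/(s_b^2+s_w^2/n_i)
    with between/within components from one-way method-of-moments, and
    subtracted.  With no between-site variance the adjustment vanishes.
    """
    Y = _as_matrix(Y)
    N, V = Y.shape
    onehot, levels, inverse = _batch_onehot(site)
    B = len(levels)
    if B < 2:
        raise ConfigurationError("nothing to harmonize: need at least 2 sites")
    n_b = onehot.sum(axis=0)
    if np.any(n_b < 2):
        raise EstimationError("each site needs at least 2 subjects")
    design = np.ones((N, 1))
    if X_keep is not None and np.asarray(X_keep).size:
        X = np.asarray(X_keep, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.hstack([design, X])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef

    site_mean = (onehot.T @ resid) / n_b[:, None]                   # (B, V)
    ss_within = ((resid - site_mean[inverse]) ** 2).sum(axis=0)     # (V,)
    ms_within = ss_within / (N - B)
    grand = resid.mean(axis=0)
    ss_between = (n_b[:, None] * (site_mean - grand[None, :]) ** 2).sum(axis=0)
    ms_between = ss_between / (B - 1)
    n0 = (N - (n_b**2).sum() / N) / (B - 1)
    sigma_b2 = np.maximum((ms_between - ms_within) / n0, 0.0)       # (V,)
    lam = sigma_b2[None, :] / (sigma_b2[None, :] + ms_within[None, :] / n_b[:, None])
    return Y - (lam * site_mean)[inverse]
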