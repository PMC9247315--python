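"""Location/scale (ComBat) batch harmonization with empirical-Bayes shrinkage.

Model, feature ``v``, subject ``j`` in batch ``i``::

    y_ijv = alpha_v + x_ij' beta_v + gamma_iv + delta_iv * eps_ijv

``alpha_v`` is the grand intercept, ``beta_v`` the covariate slopes (the
biological variance to preserve), ``gamma_iv`` / ``delta_iv`` the per-batch
additive and multiplicative effects.  Estimation:

1. feature-wise least squares on [batch indicators | covariates], with the
   grand intercept defined as the batch-size-weighted mean of batch means;
2. ``sigma_v^2`` = mean squared residual over all subjects;
3. standardize ``z_ijv = (y_ijv - alpha_v - x_ij' beta_v) / sigma_v``;
4. ``gamma_hat_iv`` = batch mean of ``z``; ``delta_hat_iv^2`` = within-batch
   variance of ``z``;
5. optionally shrink via parametric empirical Bayes (normal prior on gamma,
   inverse-gamma prior on delta^2, method-of-moments hyperparameters,
   fixed-point iteration of the conditional posterior means).

The adjusted data are ``sigma_v * (z - gamma*_iv)/delta*_iv + alpha_v +
x'beta_v``: batch location and scale are removed, covariate-associated
variance is restored.

With ``eb=False`` the raw per-batch estimates are used directly (the mode
appropriate when features are fewer than subjects, e.g. harmonizing a single
network metric).

Within-batch variances use the 1/n convention by default (``delta_ddof=0``),
which makes single-batch harmonization the exact identity and maps a pure
batch shift to exactly equal batch means; ``delta_ddof=1`` reproduces the
1/(n-1) convention of the R reference implementations.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationModel",
    "CombatError",
    "ConvergenceError",
    "fit",
    "transform",
    "harmonize",
    "eb_posterior_iteration",
]


class CombatError(ValueError):
    """Invalid input to the harmonization model."""


class ConvergenceError(RuntimeError):
    """Empirical-Bayes fixed-point iteration failed to converge."""


@dataclasses.dataclass
class HarmonizationModel:
    """Fitted ComBat parameters.

    Arrays indexed by (batch, feature) unless noted; ``retained`` flags the
    features that entered the fit (zero-variance features pass through
    untouched).
    """

    batches: list
    n_per_batch: np.ndarray  # (k,)
    alpha: np.ndarray  # (V_retained,) grand intercept
    beta: np.ndarray  # (p, V_retained) covariate slopes
    var_pooled: np.ndarray  # (V_retained,) sigma_v^2
    gamma_hat: np.ndarray  # (k, V_retained)
    delta_hat_sq: np.ndarray  # (k, V_retained)
    gamma_star: np.ndarray
    delta_star_sq: np.ndarray
    gamma_bar: np.ndarray | None  # (k,) EB normal-prior means
    tau_bar_sq: np.ndarray | None  # (k,) EB normal-prior variances
    lamda: np.ndarray | None  # (k,) inverse-gamma shape
    theta: np.ndarray | None  # (k,) inverse-gamma scale
    eb: bool
    delta_ddof: int
    retained: np.ndarray  # (V,) boolean
    n_covariates: int

    @property
    def n_features(self) -> int:
        return self.retained.size


def _as_matrix(data) -> tuple[np.ndarray, list | None]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr, None


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    x = np.asarray(
        covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates,
        dtype=float,
    )
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise CombatError(f"covariates have {x.shape[0]} rows for {n} subjects")
    return x


def fit(
    data,
    batch: Sequence,
    covariates=None,
    *,
    eb: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
    delta_ddof: int = 0,
) -> HarmonizationModel:
    """Estimate the location/scale model on a features x subjects table.

    Parameters
    ----------
    data:
        (V, N) array or DataFrame, features in rows, subjects in columns.
    batch:
        length-N batch (site/scanner) labels.
    covariates:
        optional (N, p) design of biological covariates to preserve
        (no intercept column; it is absorbed by the grand mean).
    eb:
        apply parametric empirical-Bayes shrinkage across features.
    """
    y, _ = _as_matrix(data)
    if not np.all(np.isfinite(y)):
        raise CombatError("non-finite values in data")
    V, N = y.shape
    batch = np.asarray(batch)
    if batch.shape[0] != N:
        raise CombatError(f"{batch.shape[0]} batch labels for {N} subjects")
    levels = list(dict.fromkeys(batch))  # first-appearance order, deterministic
    k = len(levels)
    if eb and k < 2:
        raise CombatError("empirical Bayes requires >= 2 batches")
    groups = [np.flatnonzero(batch == b) for b in levels]
    n_i = np.array([len(g) for g in groups])
    if np.any(n_i < 2):
        small = [levels[i] for i in np.flatnonzero(n_i < 2)]
        raise CombatError(f"batches with n < 2: {small}")
    x = _covariate_matrix(covariates, N)
    p = x.shape[1]

    # Constant (zero-variance) features are flagged and excluded from fitting.
    retained = (y.max(axis=1) - y.min(axis=1)) > 0
    yr = y[retained]
    Vr = yr.shape[0]
    if Vr == 0:
        raise CombatError("all features have zero variance")
    if eb and Vr < 2:
        raise CombatError("empirical Bayes requires >= 2 non-constant features")

    B = np.zeros((N, k))
    for i, g in enumerate(groups):
        B[g, i] = 1.0
    design = np.hstack([B, x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CombatError("rank-deficient design (batch indicators + covariates)")

    coef, *_ = np.linalg.lstsq(design, yr.T, rcond=None)  # (k+p, Vr)
    batch_means = coef[:k]
    beta = coef[k:]
    # Batch-size-weighted zero-sum constraint: the grand intercept is the
    # weighted mean of batch means.
    alpha = (n_i / N) @ batch_means

    fitted = design @ coef
    var_pooled = np.mean((yr.T - fitted) ** 2, axis=0)
    # relative guard: an exact fit leaves only O(eps^2) roundoff residual
    degenerate = var_pooled <= 1e-16 * yr.var(axis=1)
    if np.any(degenerate):
        raise CombatError(
            f"{int(degenerate.sum())} feature(s) fitted exactly by the design "
            "(zero residual variance, e.g. constant within every batch); "
            "standardization is undefined — drop the feature or add subjects"
        )

    stand_mean = alpha[None, :] + x @ beta  # (N, Vr)
    z = (yr.T - stand_mean) / np.sqrt(var_pooled)  # (N, Vr)

    gamma_hat = np.stack([z[g].mean(axis=0) for g in groups])
    delta_hat_sq = np.stack([z[g].var(axis=0, ddof=delta_ddof) for g in groups])
    zero_var = delta_hat_sq <= 1e-12  # z is standardized, so delta is O(1)
    if np.any(zero_var.all(axis=1)):
        bad = [levels[i] for i in np.flatnonzero(zero_var.all(axis=1))]
        raise CombatError(
            f"batches with zero within-batch variance on all features: {bad}; "
            "harmonization cannot estimate a scale effect there"
        )

    if eb:
        gamma_bar = gamma_hat.mean(axis=1)
        tau_bar_sq = gamma_hat.var(axis=1, ddof=1)
        m = delta_hat_sq.mean(axis=1)
        s2 = delta_hat_sq.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lamda = (2 * s2 + m**2) / s2
            theta = (m * s2 + m**3) / s2
        gamma_star = np.empty_like(gamma_hat)
        delta_star_sq = np.empty_like(delta_hat_sq)
        for i in range(k):
            gamma_star[i], delta_star_sq[i] = eb_posterior_iteration(
                gamma_hat[i],
                delta_hat_sq[i],
                n=n_i[i],
                gamma_bar=gamma_bar[i],
                tau_bar_sq=tau_bar_sq[i],
                lamda=lamda[i],
                theta=theta[i],
                tol=tol,
                max_iter=max_iter,
                delta_ddof=delta_ddof,
            )
    else:
        if np.any(zero_var):
            bad = [
                (levels[i], int(v))
                for i, v in zip(*np.nonzero(zero_var))
            ]
            raise CombatError(
                f"zero within-batch variance for (batch, feature) {bad[:5]}; "
                "with eb=False the scale adjustment divides by zero — drop the "
                "feature or merge the degenerate batch"
            )
        gamma_bar = tau_bar_sq = lamda = theta = None
        gamma_star = gamma_hat.copy()
        delta_star_sq = delta_hat_sq.copy()

    return HarmonizationModel(
        batches=levels,
        n_per_batch=n_i,
        alpha=alpha,
        beta=beta,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_hat_sq=delta_hat_sq,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        gamma_bar=gamma_bar,
        tau_bar_sq=tau_bar_sq,
        lamda=lamda,
        theta=theta,
        eb=eb,
        delta_ddof=delta_ddof,
        retained=retained,
        n_covariates=p,
    )


def eb_posterior_iteration(
    gamma_hat: np.ndarray,
    delta_hat_sq: np.ndarray,
    *,
    n: int,
    gamma_bar: float,
    tau_bar_sq: float,
    lamda: float,
    theta: float,
    tol: float = 1e-4,
    max_iter: int = 100,
    delta_ddof: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point iteration of the parametric EB conditional posterior means.

    For one batch across its features::

        gamma* = (tau^2 n gamma_hat + delta*^2 gamma_bar) / (tau^2 n + delta*^2)
        delta*^2 = (theta + 0.5 sum_j (z_j - gamma*)^2) / (n/2 + lamda - 1)

    where ``sum_j (z_j - gamma*)^2 = (n - ddof) delta_hat^2 + n (gamma_hat -
    gamma*)^2``.  Convergence: max absolute change across both parameter sets
    below ``tol``.  Shrinkage places each ``gamma*`` between ``gamma_hat`` and
    ``gamma_bar``.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    delta_hat_sq = np.asarray(delta_hat_sq, dtype=float)
    if gamma_hat.size < 2:
        raise CombatError("EB shrinkage is cross-feature; need >= 2 features")
    if tol <= 0:
        raise CombatError("tol must be positive")
    g_old = gamma_hat.copy()
    d_old = delta_hat_sq.copy()
    ss_within = (n - delta_ddof) * delta_hat_sq
    for _ in range(max_iter):
        g_new = (tau_bar_sq * n * gamma_hat + d_old * gamma_bar) / (
            tau_bar_sq * n + d_old
        )
        sum2 = ss_within + n * (gamma_hat - g_new) ** 2
        d_new = (theta + 0.5 * sum2) / (n / 2.0 + lamda - 1.0)
        change = max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old)))
        g_old, d_old = g_new, d_new
        if change < tol:
            return g_new, d_new
    raise ConvergenceError(
        f"EB iteration did not converge in {max_iter} iterations "
        f"(last max change {change:.3g})"
    )


def transform(model: HarmonizationModel, data, batch, covariates=None) -> np.ndarray:
    """Apply a fitted model: remove batch location/scale, keep covariates.

    Returns an array shaped like ``data``; features excluded at fit time are
    passed through unchanged.
    """
    y, _ = _as_matrix(data)
    V, N = y.shape
    if V != model.n_features:
        raise CombatError(
            f"feature-count mismatch: model has {model.n_features}, data has {V}"
        )
    batch = np.asarray(batch)
    unseen = set(batch) - set(model.batches)
    if unseen:
        raise CombatError(f"unseen batch labels: {sorted(map(str, unseen))}")
    x = _covariate_matrix(covariates, N)
    if x.shape[1] != model.n_covariates:
        raise CombatError(
            f"covariate-count mismatch: model has {model.n_covariates}, got {x.shape[1]}"
        )

    yr = y[model.retained]
    stand_mean = model.alpha[None, :] + x @ model.beta  # (N, Vr)
    z = (yr.T - stand_mean) / np.sqrt(model.var_pooled)
    out_r = np.empty_like(z)
    for i, b in enumerate(model.batches):
        idx = np.flatnonzero(batch == b)
        if idx.size == 0:
            continue
        out_r[idx] = (z[idx] - model.gamma_star[i]) / np.sqrt(model.delta_star_sq[i])
    out_r = out_r * np.sqrt(model.var_pooled) + stand_mean

    out = y.copy()
    out[model.retained] = out_r.T
    return out


def harmonize(data, batch, covariates=None, **fit_kwargs) -> np.ndarray:
    """Convenience ``transform(fit(...))`` on the same data."""
    model = fit(data, batch, covariates, **fit_kwargs)
    return transform(model, data, batch, covariates)
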