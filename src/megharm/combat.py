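"""ComBat harmonization: standardization, empirical-Bayes shrinkage, adjustment.

The location/scale model per parcel v, study i, recording j is

    y_ijv = alpha_v + x_ij' beta_v + gamma_iv + delta_iv * eps_ijv,

with additive study effects gamma_iv and multiplicative effects delta_iv.
After removing the fitted mean surface and scaling by the pooled residual
standard deviation, study effects are estimated per study and parcel, then
shrunk toward across-parcel priors (normal for gamma, inverse-gamma for
delta^2) via the standard empirical-Bayes conditional-posterior iteration.
GAM-ComBat is the same procedure with the spline mean model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DesignSpec, FeatureTable
from .mean_models import (
    MeanModelFit,
    SmoothSpec,
    fit_gam_mean,
    fit_linear_mean,
    predict_mean,
)

DELTA2_FLOOR = 1e-12


@dataclass
class BatchEffects:
    """Per-study, per-parcel additive/multiplicative estimates and posteriors.

    ``gamma_hat``/``delta2_hat`` are the raw within-study estimates from
    standardized data; ``gamma_star``/``delta2_star`` the EB posteriors
    (equal to the raw estimates exactly when ``eb_enabled`` is False).
    ``hyper`` holds per-study (gamma_bar, tau2, lambda, theta).
    """

    batch_levels: list[str]
    n_per_batch: np.ndarray
    gamma_hat: np.ndarray     # M x V
    delta2_hat: np.ndarray    # M x V
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    hyper: pd.DataFrame | None
    eb_enabled: bool
    iterations: int = 0

    def __post_init__(self) -> None:
        if (self.delta2_hat <= 0).any() or (self.delta2_star <= 0).any():
            raise ValueError("multiplicative effect estimates must be positive")


def standardize(Y: np.ndarray, fit: MeanModelFit, table: FeatureTable) -> np.ndarray:
    """Z = (Y - fitted mean surface) / pooled residual SD; batch effects remain."""
    Y = np.asarray(Y, dtype=float)
    zero = fit.sigma2 <= 0
    if zero.any():
        raise ValueError(
            f"zero pooled residual variance in parcel index {int(np.nonzero(zero)[0][0])}"
        )
    return (Y - predict_mean(fit, table)) / fit.sigma[None, :]


def estimate_batch_effects(Z: np.ndarray, batch: np.ndarray) -> BatchEffects:
    """Within-study mean and (n-1) variance of standardized data, per parcel."""
    Z = np.asarray(Z, dtype=float)
    batch = np.asarray(batch)
    levels = list(dict.fromkeys(batch))
    m, v = len(levels), Z.shape[1]
    gamma = np.empty((m, v))
    delta2 = np.empty((m, v))
    n_per = np.empty(m, dtype=int)
    for i, b in enumerate(levels):
        block = Z[batch == b]
        if block.shape[0] < 2:
            raise ValueError(f"study {b!r} has fewer than 2 recordings")
        n_per[i] = block.shape[0]
        gamma[i] = block.mean(axis=0)
        delta2[i] = block.var(axis=0, ddof=1)
    if (delta2 <= 0).any():
        warnings.warn(
            "zero within-study variance floored to a small epsilon", UserWarning
        )
        delta2 = np.maximum(delta2, DELTA2_FLOOR)
    return BatchEffects(
        batch_levels=[str(b) for b in levels],
        n_per_batch=n_per,
        gamma_hat=gamma,
        delta2_hat=delta2,
        gamma_star=gamma.copy(),
        delta2_star=delta2.copy(),
        hyper=None,
        eb_enabled=False,
    )


def inverse_gamma_moments(m: float, s2: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) of an inverse gamma from mean m, variance s2."""
    lam = (m**2 + 2.0 * s2) / s2
    theta = (m**3 + m * s2) / s2
    return lam, theta


def eb_shrink(
    effects: BatchEffects,
    Z: np.ndarray,
    batch: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> BatchEffects:
    """Shrink study effects toward across-parcel priors, per study.

    Hyperparameters by method of moments across parcels; then the standard
    conditional posterior means are iterated to a fixed point:

        gamma* = (n_i tau2 gamma_hat + delta2* gamma_bar) / (n_i tau2 + delta2*)
        delta2* = (theta + 0.5 sum_j (Z_ij - gamma*)^2) / (n_i/2 + lambda - 1)
    """
    Z = np.asarray(Z, dtype=float)
    batch = np.asarray(batch)
    v = effects.gamma_hat.shape[1]
    if v < 2:
        raise ValueError("empirical-Bayes shrinkage needs at least 2 parcels")
    gamma_star = effects.gamma_hat.copy()
    delta2_star = effects.delta2_hat.copy()
    batch_str = np.asarray([str(x) for x in batch])
    hyper_rows = []
    total_iters = 0
    for i, b in enumerate(effects.batch_levels):
        g_hat = effects.gamma_hat[i]
        d_hat = effects.delta2_hat[i]
        g_bar = float(g_hat.mean())
        tau2 = float(g_hat.var(ddof=1))
        m_i = float(d_hat.mean())
        s2_i = float(d_hat.var(ddof=1))
        if s2_i <= 0 or tau2 <= 0:
            warnings.warn(
                f"degenerate across-parcel spread for study {b!r}; "
                "no shrinkage applied",
                UserWarning,
            )
            hyper_rows.append((g_bar, tau2, np.nan, np.nan))
            continue
        lam, theta = inverse_gamma_moments(m_i, s2_i)
        block = Z[batch_str == b]
        n_i = block.shape[0]
        g = g_hat.copy()
        d = d_hat.copy()
        change = np.inf
        it = 0
        while change >= tol:
            if it >= max_iter:
                raise RuntimeError(
                    f"EB iteration for study {b!r} did not converge within "
                    f"{max_iter} iterations (last change {change:.3g})"
                )
            g_new = (n_i * tau2 * g_hat + d * g_bar) / (n_i * tau2 + d)
            sse = np.sum((block - g_new[None, :]) ** 2, axis=0)
            d_new = (theta + 0.5 * sse) / (n_i / 2.0 + lam - 1.0)
            change = max(np.abs(g_new - g).max(), np.abs(d_new - d).max())
            g, d = g_new, d_new
            it += 1
        total_iters = max(total_iters, it)
        gamma_star[i] = g
        delta2_star[i] = d
        hyper_rows.append((g_bar, tau2, lam, theta))
    hyper = pd.DataFrame(
        hyper_rows,
        index=effects.batch_levels,
        columns=["gamma_bar", "tau2", "lambda", "theta"],
    )
    return BatchEffects(
        batch_levels=effects.batch_levels,
        n_per_batch=effects.n_per_batch,
        gamma_hat=effects.gamma_hat,
        delta2_hat=effects.delta2_hat,
        gamma_star=gamma_star,
        delta2_star=np.maximum(delta2_star, DELTA2_FLOOR),
        hyper=hyper,
        eb_enabled=True,
        iterations=total_iters,
    )


def _expand(effects: BatchEffects, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-record gamma*/delta* rows aligned with the data."""
    index = {b: i for i, b in enumerate(effects.batch_levels)}
    rows = np.array([index[str(b)] for b in batch])
    return effects.gamma_star[rows], np.sqrt(effects.delta2_star[rows])


def apply_combat(
    Y: np.ndarray, fit: MeanModelFit, effects: BatchEffects, table: FeatureTable
) -> np.ndarray:
    """y* = sigma_v (Z - gamma*)/delta* + alpha_v + covariate contribution."""
    Y = np.asarray(Y, dtype=float)
    batch = table.study
    Z = standardize(Y, fit, table)
    if Z.shape[1] != effects.gamma_star.shape[1]:
        raise ValueError("parcel count mismatch between data and batch effects")
    g, d = _expand(effects, batch)
    adjusted = (Z - g) / d
    return fit.sigma[None, :] * adjusted + predict_mean(fit, table)


def harmonize_combat(
    table: FeatureTable,
    spec: DesignSpec | None = None,
    mean_model: str = "linear",
    eb: bool = True,
    smooth: SmoothSpec | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    return_model: bool = False,
):
    """End-to-end ComBat (``mean_model='linear'``) or GAM-ComBat (``'gam'``).

    The linear default uses cubic polynomial age terms plus sex and
    condition; the GAM variant smooths age and keeps sex/condition linear.
    """
    Y = table.values
    if spec is None:
        spec = DesignSpec(age_degree=3) if mean_model == "linear" else DesignSpec(
            age_degree=1, smooth_age=True
        )
    if mean_model == "linear":
        fit = fit_linear_mean(Y, table, spec)
    elif mean_model == "gam":
        fit = fit_gam_mean(Y, table, spec, smooth)
    else:
        raise ValueError(f"unknown mean_model {mean_model!r}")
    Z = standardize(Y, fit, table)
    effects = estimate_batch_effects(Z, table.study)
    if eb:
        effects = eb_shrink(effects, Z, table.study, tol=tol, max_iter=max_iter)
    out = apply_combat(Y, fit, effects, table)
    result = table.with_values(out)
    if return_model:
        return result, fit, effects
    return result
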