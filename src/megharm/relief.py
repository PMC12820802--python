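"""RELIEF-style harmonization via structured matrix decomposition.

The recordings-by-parcels matrix is decomposed as

    Y = A + beta X' + [Gamma_1; ...; Gamma_M] + R + [I_1; ...; I_M] + [d_1 E_1; ...; d_M E_M]

intercepts, optional covariate effects, per-study mean blocks, shared
low-rank variation R, study-specific latent low-rank blocks I_m, and noise
with study-specific scales d_m. Harmonization keeps the intercepts,
covariate term, shared variation, and the noise homogenized to the pooled
scale, and discards the study means and study-specific latent blocks.

The shared/latent split is estimated by alternating truncated SVDs with a
Marchenko-Pastur singular-value edge rule deciding the retained rank. By
default no covariates enter the model (nonlinear and unknown covariate
structure is carried by the shared-variation term instead); the evaluation
stage residualizes covariates downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

from .core_data import DesignSpec, FeatureTable, covariate_columns


# -- Marchenko-Pastur edge rule -------------------------------------------

@lru_cache(maxsize=64)
def _mp_median(beta: float) -> float:
    """Median of the standard Marchenko-Pastur eigenvalue law with ratio beta <= 1."""
    a, b = (1.0 - np.sqrt(beta)) ** 2, (1.0 + np.sqrt(beta)) ** 2

    def dens(x):
        return np.sqrt(np.maximum((b - x) * (x - a), 0.0)) / (2.0 * np.pi * beta * x)

    def cdf(x):
        val, _ = integrate.quad(dens, a, x, limit=200)
        return val

    return float(optimize.brentq(lambda x: cdf(x) - 0.5, a + 1e-9, b - 1e-9))


def estimate_noise_sd(M: np.ndarray) -> float:
    """Noise scale from the median singular value against the MP median.

    Robust to a few large signal components: the median singular value of a
    noise-dominated matrix sits at sigma * sqrt(n_max * mp_median(beta)).
    """
    n, p = M.shape
    s = np.linalg.svd(M, compute_uv=False)
    n_max, n_min = max(n, p), min(n, p)
    beta = n_min / n_max
    med = _mp_median(round(beta, 6))
    return float(np.median(s) / np.sqrt(n_max * med))


def _sv_threshold(n: int, p: int, sigma: float, edge_buffer: float) -> float:
    return sigma * (np.sqrt(n) + np.sqrt(p)) * (1.0 + edge_buffer)


def _truncate(M: np.ndarray, thresh: float) -> tuple[np.ndarray, int]:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    k = int(np.sum(s > thresh))
    if k == 0:
        return np.zeros_like(M), 0
    return (U[:, :k] * s[:k]) @ Vt[:k], k


# -- decomposition container ----------------------------------------------

@dataclass
class ReliefDecomposition:
    """All components of the fitted decomposition; their sum reproduces the input."""

    intercept: np.ndarray            # A row vector per parcel
    beta: np.ndarray | None          # covariate coefficients (p_cov x parcels) or None
    covariate_names: list[str] = field(default_factory=list)
    gamma: np.ndarray | None = None  # M x parcels study means
    batch_levels: list[str] = field(default_factory=list)
    delta: np.ndarray | None = None  # per-study residual scale factors
    shared: np.ndarray | None = None          # R* in scaled units
    site_latent: np.ndarray | None = None     # concatenated I* blocks, scaled units
    noise: np.ndarray | None = None           # E in scaled units
    shared_rank: int = 0
    site_ranks: dict[str, int] = field(default_factory=dict)
    iterations: int = 0
    converged: bool = True
    noise_sd: float = 0.0


# -- stages ----------------------------------------------------------------

def relief_regress(
    Y: np.ndarray,
    batch: np.ndarray,
    table: FeatureTable | None = None,
    spec: DesignSpec | None = None,
):
    """Two-stage regression: pooled covariate fit, then per-study residual means.

    Returns ``(A, beta, gamma, resid, levels)`` with A the per-parcel
    intercepts, beta the covariate coefficients (None when no covariates),
    gamma the per-study mean blocks, and resid = Y - A - X beta - Gamma
    (per-study residual column means are exactly zero).
    """
    Y = np.asarray(Y, dtype=float)
    batch = np.asarray(batch)
    levels = list(dict.fromkeys(batch))
    if spec is not None:
        if table is None:
            raise ValueError("a FeatureTable is required to build covariates")
        X, names = covariate_columns(table, spec)
        D = np.column_stack([np.ones(len(Y)), X])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("rank-deficient covariate design")
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        A = coef[0]
        beta = coef[1:]
        stage1 = Y - D @ coef
    else:
        names = []
        A = Y.mean(axis=0)
        beta = None
        stage1 = Y - A[None, :]
    gamma = np.empty((len(levels), Y.shape[1]))
    resid = stage1.copy()
    for i, b in enumerate(levels):
        mask = batch == b
        if mask.sum() < 2:
            raise ValueError(f"study {b!r} has fewer than 2 recordings")
        gamma[i] = stage1[mask].mean(axis=0)
        resid[mask] -= gamma[i]
    return A, beta, names, gamma, resid, [str(b) for b in levels]


def relief_scale(resid: np.ndarray, batch: np.ndarray):
    """Scale each study block so mean residual variances agree across studies.

    delta_m = sqrt(study-mean variance / pooled-mean variance); blocks are
    divided by delta_m. Returns ``(scaled, delta, levels)``.
    """
    resid = np.asarray(resid, dtype=float)
    batch = np.asarray(batch)
    levels = list(dict.fromkeys(batch))
    pooled = float(np.mean(resid**2))
    if pooled <= 0:
        raise ValueError("zero pooled residual variance")
    delta = np.empty(len(levels))
    scaled = resid.copy()
    for i, b in enumerate(levels):
        mask = batch == b
        v_m = float(np.mean(resid[mask] ** 2))
        if v_m <= 0:
            raise ValueError(f"zero residual variance in study {b!r}")
        delta[i] = np.sqrt(v_m / pooled)
        scaled[mask] /= delta[i]
    return scaled, delta, [str(b) for b in levels]


def relief_decompose(
    scaled: np.ndarray,
    batch: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
    edge_buffer: float = 0.05,
    noise_sd: float | None = None,
):
    """Alternate truncated SVDs for shared (R*) and per-study latent (I*) terms.

    Rank per truncation is chosen by the Marchenko-Pastur singular-value
    edge (with a small finite-size buffer). Returns
    ``(R, I, E, info)`` where E is the final remainder and ``info`` carries
    ranks, iteration count, convergence flag and the noise scale used.
    """
    M = np.asarray(scaled, dtype=float)
    batch = np.asarray(batch)
    levels = list(dict.fromkeys(batch))
    n, p = M.shape
    sigma = estimate_noise_sd(M) if noise_sd is None else noise_sd
    t_full = _sv_threshold(n, p, sigma, edge_buffer)

    I = np.zeros_like(M)
    R, shared_rank = _truncate(M, t_full)
    site_ranks = {str(b): 0 for b in levels}
    converged = False
    it = 0
    norm = np.linalg.norm(M) or 1.0
    for it in range(1, max_iter + 1):
        I_new = np.zeros_like(M)
        for b in levels:
            mask = batch == b
            block = M[mask] - R[mask]
            t_block = _sv_threshold(int(mask.sum()), p, sigma, edge_buffer)
            I_new[mask], site_ranks[str(b)] = _truncate(block, t_block)
        R_new, shared_rank = _truncate(M - I_new, t_full)
        change = (
            np.linalg.norm(R_new - R) + np.linalg.norm(I_new - I)
        ) / norm
        R, I = R_new, I_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RELIEF decomposition did not converge within {max_iter} iterations",
            UserWarning,
        )
    E = M - R - I
    info = {
        "shared_rank": shared_rank,
        "site_ranks": site_ranks,
        "iterations": it,
        "converged": converged,
        "noise_sd": sigma,
    }
    return R, I, E, info


def relief_fit(
    table: FeatureTable,
    spec: DesignSpec | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    edge_buffer: float = 0.05,
) -> ReliefDecomposition:
    """Run regression, scaling and decomposition; return all components."""
    Y = table.values
    batch = table.study
    A, beta, names, gamma, resid, levels = relief_regress(Y, batch, table, spec)
    scaled, delta, _ = relief_scale(resid, batch)
    R, I, E, info = relief_decompose(
        scaled, batch, tol=tol, max_iter=max_iter, edge_buffer=edge_buffer
    )
    return ReliefDecomposition(
        intercept=A,
        beta=beta,
        covariate_names=names,
        gamma=gamma,
        batch_levels=levels,
        delta=delta,
        shared=R,
        site_latent=I,
        noise=E,
        shared_rank=info["shared_rank"],
        site_ranks=info["site_ranks"],
        iterations=info["iterations"],
        converged=info["converged"],
        noise_sd=info["noise_sd"],
    )


def relief_reassemble(
    decomp: ReliefDecomposition,
    table: FeatureTable,
    spec: DesignSpec | None = None,
    pooled_shared_scale: bool = False,
) -> np.ndarray:
    """Harmonized data: intercepts + covariates + shared variation + pooled noise.

    Study-mean blocks and study-latent blocks are discarded. As printed in
    the model, each study's shared-variation block is rescaled by its own
    delta_m; ``pooled_shared_scale=True`` instead applies the common
    (pooled, = 1 in scaled units) factor, avoiding re-introduction of scale
    heterogeneity through R*.
    """
    batch = table.study
    out = np.tile(decomp.intercept, (len(batch), 1)).astype(float)
    if decomp.beta is not None:
        X, names = covariate_columns(table, spec, strict=False)
        if names != decomp.covariate_names:
            raise ValueError("covariate mismatch with the fitted decomposition")
        out += X @ decomp.beta
    shared = decomp.shared.copy()
    if not pooled_shared_scale:
        for i, b in enumerate(decomp.batch_levels):
            mask = np.asarray([str(x) for x in batch]) == b
            shared[mask] *= decomp.delta[i]
    out += shared + decomp.noise
    return out


def harmonize_relief(
    table: FeatureTable,
    spec: DesignSpec | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    edge_buffer: float = 0.05,
    pooled_shared_scale: bool = False,
    return_model: bool = False,
):
    """End-to-end RELIEF harmonization (no explicit covariates by default)."""
    decomp = relief_fit(
        table, spec, tol=tol, max_iter=max_iter, edge_buffer=edge_buffer
    )
    out = relief_reassemble(decomp, table, spec, pooled_shared_scale)
    result = table.with_values(out)
    if return_model:
        return result, decomp
    return result
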