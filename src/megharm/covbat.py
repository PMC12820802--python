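"""GAM-CovBat: second-stage harmonization of residual covariance.

Stage 1 is GAM-ComBat. Its residuals (harmonized values minus the fitted
mean surface) are decomposed by PCA; the leading principal-component
scores — the smallest set explaining at least ``pct_var`` of the residual
variance — receive a further ComBat location/scale adjustment by study
(no covariates at the score stage), the trailing scores pass through, and
the adjusted residuals are reprojected and the mean surface added back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import DesignSpec, FeatureTable
from .combat import (
    BatchEffects,
    apply_combat,
    eb_shrink,
    estimate_batch_effects,
    harmonize_combat,
)
from .mean_models import MeanModelFit, SmoothSpec, predict_mean


@dataclass
class CovbatFit:
    """PCA of stage-1 residuals plus the score-level adjustment parameters."""

    eigenvectors: np.ndarray        # q x parcels, rows are components
    eigenvalues: np.ndarray         # length q, residual covariance normalized by N
    explained_fraction: np.ndarray
    rank: int
    n_adjusted: int
    pct_var: float
    center: np.ndarray              # per-parcel residual means removed before PCA
    score_effects: BatchEffects | None


def covbat_residuals(
    Y: np.ndarray, fit: MeanModelFit, effects: BatchEffects, table: FeatureTable
) -> np.ndarray:
    """Stage-1 residuals: ComBat-adjusted data minus the fitted mean surface."""
    return apply_combat(Y, fit, effects, table) - predict_mean(fit, table)


def _pca(resid: np.ndarray):
    """SVD-based PCA; covariance normalized by N, deterministic sign convention."""
    n = resid.shape[0]
    center = resid.mean(axis=0)
    R = resid - center
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size else np.zeros(0, dtype=bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # sign convention: largest-magnitude loading of each eigenvector positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    eigvals = s**2 / n
    scores = U * s  # n x q
    return center, scores, Vt, eigvals


def n_components_for(eigvals: np.ndarray, pct_var: float) -> int:
    """Smallest K with cumulative explained variance >= pct_var (ties -> smaller K)."""
    if eigvals.size == 0:
        return 0
    frac = np.cumsum(eigvals) / eigvals.sum()
    if pct_var <= 0:
        return 0
    return int(np.searchsorted(frac, pct_var - 1e-12) + 1)


def harmonize_covbat(
    table: FeatureTable,
    spec: DesignSpec | None = None,
    pct_var: float = 0.95,
    eb: bool = True,
    score_eb: bool = True,
    smooth: SmoothSpec | None = None,
    return_model: bool = False,
):
    """GAM-ComBat followed by ComBat on leading principal-component scores.

    ``pct_var`` in [0, 1] selects how much residual variance is harmonized
    (0 leaves stage-1 output untouched; 1 adjusts every component).
    ``score_eb`` toggles empirical-Bayes shrinkage at the score stage.
    """
    if not 0.0 <= pct_var <= 1.0:
        raise ValueError("pct_var must lie in [0, 1]")
    stage1, fit, effects = harmonize_combat(
        table, spec, mean_model="gam", eb=eb, smooth=smooth, return_model=True
    )
    mean_surface = predict_mean(fit, table)
    resid = stage1.values - mean_surface

    if table.n_parcels > table.n_records - 1:
        warnings.warn(
            "more parcels than records: PCA rank capped at records - 1", UserWarning
        )
    center, scores, Vt, eigvals = _pca(resid)
    q = len(eigvals)
    K = n_components_for(eigvals, pct_var)

    score_effects = None
    if K == 0:
        out = stage1.values
    else:
        sub = scores[:, :K]
        score_sd = sub.std(axis=0, ddof=0)
        Zs = (sub - sub.mean(axis=0)) / score_sd  # standardized scores
        se = estimate_batch_effects(Zs, table.study)
        if score_eb and K >= 2:
            try:
                se = eb_shrink(se, Zs, table.study)
            except ValueError:
                warnings.warn("score-stage EB skipped (too few scores)", UserWarning)
        elif score_eb and K < 2:
            warnings.warn(
                "score-stage EB needs >= 2 adjusted components; skipped", UserWarning
            )
        idx = {b: i for i, b in enumerate(se.batch_levels)}
        rows = np.array([idx[str(b)] for b in table.study])
        adj = (Zs - se.gamma_star[rows]) / np.sqrt(se.delta2_star[rows])
        sub_adj = adj * score_sd + sub.mean(axis=0)
        resid_adj = sub_adj @ Vt[:K] + scores[:, K:] @ Vt[K:] + center
        out = resid_adj + mean_surface
        score_effects = se

    result = table.with_values(out)
    if return_model:
        model = CovbatFit(
            eigenvectors=Vt,
            eigenvalues=eigvals,
            explained_fraction=eigvals / eigvals.sum() if q else eigvals,
            rank=q,
            n_adjusted=K,
            pct_var=pct_var,
            center=center,
            score_effects=score_effects,
        )
        return result, fit, effects, model
    return result
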