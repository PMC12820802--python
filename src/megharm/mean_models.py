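"""Per-parcel mean-structure fits shared by the harmonizers.

Both fits estimate, per parcel, an intercept, covariate effects and study
(batch) intercepts jointly, under the standard ComBat identification
constraint: the grand intercept is the sample-size-weighted mean of the
batch-level intercepts. The linear fit uses raw polynomial age terms; the
GAM fit replaces the age polynomial by a penalized cubic B-spline (P-spline:
second-difference penalty, 10 basis functions with knots at age quantiles,
penalty weight chosen once by generalized cross-validation on the
parcel-mean response and then held fixed across parcels). The pooled
residual variance sigma_v^2 uses the divide-by-N convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .core_data import DesignSpec, FeatureTable, covariate_columns


def _one_hot(batch: np.ndarray):
    """Batch indicator matrix (n x M) and the batch levels in first-appearance order."""
    levels = list(dict.fromkeys(batch))
    B = np.column_stack([(batch == b).astype(float) for b in levels])
    return B, levels


@dataclass
class SmoothSpec:
    """Cubic B-spline basis configuration for the age smooth."""

    n_basis: int = 10
    degree: int = 3
    penalty: float | None = None        # None -> select by GCV
    penalty_grid: tuple[float, float, int] = (-4.0, 8.0, 40)  # log10 lo, hi, count
    per_parcel_penalty: bool = False


@dataclass
class MeanModelFit:
    """Per-parcel intercept/covariate surface with pooled residual scale.

    ``kind`` is ``linear`` (polynomial age terms from a :class:`DesignSpec`)
    or ``gam`` (spline age smooth, linear sex/condition). Prediction is
    reproducible from the stored representation alone; ages outside the
    training range are clamped, not extrapolated.
    """

    kind: str
    alpha: np.ndarray                    # per-parcel grand intercept
    coef: np.ndarray                     # covariate coefficients, p_cov x parcels
    covariate_names: list[str]
    sigma2: np.ndarray                   # per-parcel pooled residual variance (divide by N)
    spec: DesignSpec
    batch_levels: list[str] = field(default_factory=list)
    age_range: tuple[float, float] | None = None
    # spline representation (gam only)
    knots: np.ndarray | None = None
    spline_degree: int = 3
    basis_center: np.ndarray | None = None   # training column means of the basis
    spline_coef: np.ndarray | None = None    # n_basis x parcels
    penalty: float | np.ndarray | None = None

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.sigma2)

    # -- (de)serialization -------------------------------------------------
    def to_json(self, path) -> None:
        def enc(x):
            return None if x is None else np.asarray(x).tolist()

        payload = {
            "kind": self.kind,
            "alpha": enc(self.alpha),
            "coef": enc(self.coef),
            "covariate_names": self.covariate_names,
            "sigma2": enc(self.sigma2),
            "spec": {
                "age_degree": self.spec.age_degree,
                "smooth_age": self.spec.smooth_age,
                "include_age": self.spec.include_age,
                "include_sex": self.spec.include_sex,
                "include_condition": self.spec.include_condition,
            },
            "batch_levels": list(self.batch_levels),
            "age_range": list(self.age_range) if self.age_range else None,
            "knots": enc(self.knots),
            "spline_degree": self.spline_degree,
            "basis_center": enc(self.basis_center),
            "spline_coef": enc(self.spline_coef),
            "penalty": enc(self.penalty),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MeanModelFit":
        with open(path) as fh:
            d = json.load(fh)

        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            kind=d["kind"],
            alpha=arr(d["alpha"]),
            coef=arr(d["coef"]),
            covariate_names=d["covariate_names"],
            sigma2=arr(d["sigma2"]),
            spec=DesignSpec(**d["spec"]),
            batch_levels=d["batch_levels"],
            age_range=tuple(d["age_range"]) if d["age_range"] else None,
            knots=arr(d["knots"]),
            spline_degree=d["spline_degree"],
            basis_center=arr(d["basis_center"]),
            spline_coef=arr(d["spline_coef"]),
            penalty=d["penalty"],
        )


# -- linear fit ------------------------------------------------------------

def fit_linear_mean(
    Y: np.ndarray, table: FeatureTable, spec: DesignSpec, batch: np.ndarray | None = None
) -> MeanModelFit:
    """Least-squares fit of batch intercepts + covariates per parcel.

    The stored intercept is the sample-size-weighted mean of the batch
    intercepts; batch deviations themselves are left for the harmonizer to
    estimate from standardized data.
    """
    Y = np.asarray(Y, dtype=float)
    if batch is None:
        batch = table.study
    B, levels = _one_hot(np.asarray(batch))
    X_cov, names = covariate_columns(table, spec)
    D = np.column_stack([B, X_cov])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError(
            "rank-deficient design: batch indicators plus covariates "
            f"{['batch:' + str(b) for b in levels] + names} have rank {rank} < {D.shape[1]}"
        )
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    m = B.shape[1]
    n_i = B.sum(axis=0)
    alpha = (n_i / n_i.sum()) @ beta[:m]
    resid = Y - D @ beta
    sigma2 = np.mean(resid**2, axis=0)
    ages = table.data["age"].to_numpy(dtype=float)
    return MeanModelFit(
        kind="linear",
        alpha=alpha,
        coef=beta[m:],
        covariate_names=names,
        sigma2=sigma2,
        spec=spec,
        batch_levels=[str(b) for b in levels],
        age_range=(float(ages.min()), float(ages.max())) if len(ages) else None,
    )


# -- GAM fit ---------------------------------------------------------------

def _spline_knots(ages: np.ndarray, n_basis: int, degree: int) -> np.ndarray:
    """Knot vector with interior knots at age quantiles, clamped boundaries."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis too small for the spline degree")
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(np.unique(ages), qs) if n_interior else np.array([])
    lo, hi = float(ages.min()), float(ages.max())
    return np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )


def _basis(ages: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[0], knots[-1]
    clamped = np.clip(ages, lo, hi)
    return BSpline.design_matrix(clamped, knots, degree, extrapolate=False).toarray()


def _diff_penalty(knots: np.ndarray, degree: int, n_basis: int) -> np.ndarray:
    """Second-divided-difference penalty at the Greville abscissae.

    Its null space is exactly the functions linear in age, so an infinite
    penalty collapses the smooth onto the least-squares line.
    """
    greville = np.array(
        [knots[k + 1 : k + degree + 1].mean() for k in range(n_basis)]
    )
    rows = []
    for k in range(1, n_basis - 1):
        h0 = greville[k] - greville[k - 1]
        h1 = greville[k + 1] - greville[k]
        row = np.zeros(n_basis)
        row[k - 1] = 1.0 / h0
        row[k] = -(1.0 / h0 + 1.0 / h1)
        row[k + 1] = 1.0 / h1
        rows.append(row)
    D = np.asarray(rows) * (greville[-1] - greville[0]) / (n_basis - 1)
    return D.T @ D


def fit_gam_mean(
    Y: np.ndarray,
    table: FeatureTable,
    spec: DesignSpec | None = None,
    smooth: SmoothSpec | None = None,
    batch: np.ndarray | None = None,
) -> MeanModelFit:
    """Penalized-spline fit of age plus linear sex/condition and batch intercepts.

    The spline basis columns are centered (their training means are stored),
    which makes the smooth orthogonal to the intercept so batch intercepts
    stay identifiable. The penalty weight is selected by GCV on the
    parcel-mean response unless ``smooth.per_parcel_penalty`` is set.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    spec = spec or DesignSpec(age_degree=1, smooth_age=True)
    smooth = smooth or SmoothSpec()
    if batch is None:
        batch = table.study
    B, levels = _one_hot(np.asarray(batch))
    ages = table.data["age"].to_numpy(dtype=float)
    if len(np.unique(ages)) < smooth.n_basis + 2:
        raise ValueError(
            f"need at least {smooth.n_basis + 2} distinct ages for a "
            f"{smooth.n_basis}-function spline basis"
        )
    knots = _spline_knots(ages, smooth.n_basis, smooth.degree)
    basis = _basis(ages, knots, smooth.degree)
    center = basis.mean(axis=0)
    # B-splines are a partition of unity, so the centered columns sum to the
    # zero vector; absorb the identifiability constraint by working in the
    # orthogonal complement of the constant coefficient direction.
    k_full = basis.shape[1]
    ones = np.full((k_full, 1), 1.0 / np.sqrt(k_full))
    Zc = np.linalg.svd(np.eye(k_full) - ones @ ones.T)[0][:, : k_full - 1]
    basis_c = (basis - center) @ Zc

    lin_spec = DesignSpec(
        age_degree=1,
        smooth_age=False,
        include_sex=spec.include_sex,
        include_condition=spec.include_condition,
    )
    X_cov, names = covariate_columns(table, lin_spec)
    X_cov = X_cov[:, 1:]  # drop the linear age column: the smooth carries age
    names = names[1:]

    m, k = B.shape[1], basis_c.shape[1]
    D = np.column_stack([B, basis_c, X_cov])
    P = np.zeros((D.shape[1], D.shape[1]))
    P[m : m + k, m : m + k] = Zc.T @ _diff_penalty(knots, smooth.degree, k_full) @ Zc

    DtD = D.T @ D
    DtY = D.T @ Y
    n = D.shape[0]

    def solve(lam, rhs):
        return np.linalg.solve(DtD + lam * P, rhs)

    def gcv(lam, y_col):
        beta = solve(lam, D.T @ y_col)
        fitted = D @ beta
        # effective dof = trace of the hat matrix
        H_tr = np.trace(np.linalg.solve(DtD + lam * P, DtD))
        rss = float(np.sum((y_col - fitted) ** 2))
        return n * rss / (n - H_tr) ** 2

    lo, hi, cnt = smooth.penalty_grid
    grid = np.logspace(lo, hi, cnt)

    if smooth.penalty is not None:
        lam = smooth.penalty
        beta = solve(lam, DtY)
    elif smooth.per_parcel_penalty:
        lam = np.empty(Y.shape[1])
        beta = np.empty((D.shape[1], Y.shape[1]))
        for j in range(Y.shape[1]):
            scores = [gcv(g, Y[:, j]) for g in grid]
            lam[j] = grid[int(np.argmin(scores))]
            beta[:, j] = solve(lam[j], DtY[:, j])
    else:
        ybar = Y.mean(axis=1)
        scores = [gcv(g, ybar) for g in grid]
        lam = float(grid[int(np.argmin(scores))])
        beta = solve(lam, DtY)

    n_i = B.sum(axis=0)
    alpha = (n_i / n_i.sum()) @ beta[:m]
    resid = Y - D @ beta
    sigma2 = np.mean(resid**2, axis=0)
    return MeanModelFit(
        kind="gam",
        alpha=alpha,
        coef=beta[m + k :],
        covariate_names=names,
        sigma2=sigma2,
        spec=spec,
        batch_levels=[str(b) for b in levels],
        age_range=(float(ages.min()), float(ages.max())),
        knots=knots,
        spline_degree=smooth.degree,
        basis_center=center,
        spline_coef=Zc @ beta[m : m + k],
        penalty=lam,
    )


# -- prediction ------------------------------------------------------------

def predict_mean(fit: MeanModelFit, table: FeatureTable) -> np.ndarray:
    """alpha_v plus the covariate contribution per record; batch terms excluded."""
    cov = table.data
    n = len(cov)
    if fit.kind == "linear":
        X, names = covariate_columns(table, fit.spec, strict=False)
        if names != fit.covariate_names:
            raise ValueError("covariate mismatch between fit and prediction table")
        contrib = X @ fit.coef if X.shape[1] else np.zeros((n, fit.alpha.size))
    elif fit.kind == "gam":
        ages = cov["age"].to_numpy(dtype=float)
        lo, hi = fit.knots[0], fit.knots[-1]
        if (ages < lo).any() or (ages > hi).any():
            warnings.warn(
                "ages outside the training range are clamped, not extrapolated",
                UserWarning,
                stacklevel=2,
            )
        basis = _basis(ages, fit.knots, fit.spline_degree) - fit.basis_center
        contrib = basis @ fit.spline_coef
        cols = []
        if "sex" in fit.covariate_names:
            cols.append((cov["sex"] == "M").to_numpy(dtype=float))
        if "condition" in fit.covariate_names:
            cols.append((cov["condition"] == "eyes-open").to_numpy(dtype=float))
        if cols:
            contrib = contrib + np.column_stack(cols) @ fit.coef
    else:
        raise ValueError(f"unknown fit kind {fit.kind!r}")
    return fit.alpha[None, :] + contrib
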