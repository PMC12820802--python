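"""Site-effect diagnostics, covariate-retention tests, and concordance metrics.

Residual site effects are quantified per parcel by one-way ANOVA across
studies (additive effects), Levene's test on the same residuals
(multiplicative effects), the partial R^2 uniquely attributable to study,
and the mean absolute log variance ratio. Covariate retention is assessed
through eyes-open/eyes-closed t-tests in occipital ROIs, polynomial
age-fit R^2, and repeated stratified k-fold cross-validated Delta R^2
between two harmonized versions of the same recordings with paired t-tests
and Benjamini-Hochberg FDR across parcels. Map concordance across studies
within an age bin uses median pairwise Pearson r, median Lin concordance,
ICC(3,k) (consistency form), and the median across-study coefficient of
variation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .core_data import DesignSpec, FeatureTable, OCCIPITAL_ROIS, covariate_columns


# -- residualization -------------------------------------------------------

def residualize(table: FeatureTable, degree: int = 3) -> np.ndarray:
    """Pooled OLS per parcel on intercept + sex + condition + age polynomial.

    Covariates with a single observed level are dropped (a constant column
    adds nothing to the fit); residuals have zero column means.
    """
    df = table.data
    spec = DesignSpec(
        age_degree=degree,
        include_sex=df["sex"].nunique() > 1,
        include_condition=df["condition"].nunique() > 1,
    )
    X, _ = covariate_columns(table, spec)
    D = np.column_stack([np.ones(table.n_records), X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient covariate design in residualization")
    coef, *_ = np.linalg.lstsq(D, table.values, rcond=None)
    return table.values - D @ coef


# -- grouped ANOVA machinery (vectorized over parcels) ---------------------

def _group_stats(X: np.ndarray, labels: np.ndarray):
    levels = list(dict.fromkeys(labels))
    masks = [labels == b for b in levels]
    ns = np.array([m.sum() for m in masks])
    if (ns < 2).any():
        bad = levels[int(np.argmin(ns))]
        raise ValueError(f"group {bad!r} has fewer than 2 observations")
    means = np.stack([X[m].mean(axis=0) for m in masks])  # M x V
    return levels, masks, ns, means


def _anova_f(X: np.ndarray, labels: np.ndarray):
    """One-way fixed-effects ANOVA per column; returns (F, p, df_between, df_within)."""
    levels, masks, ns, means = _group_stats(X, labels)
    grand = X.mean(axis=0)
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = np.zeros(X.shape[1])
    for m, mu in zip(masks, means):
        ssw += ((X[m] - mu) ** 2).sum(axis=0)
    dfb = len(levels) - 1
    dfw = X.shape[0] - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ssw > 0, F, np.inf)
    p = stats.f.sf(F, dfb, dfw)
    return F, p, dfb, dfw


def study_anova(residuals: np.ndarray, study: np.ndarray) -> pd.DataFrame:
    """Per-parcel one-way ANOVA of study on residuals."""
    F, p, dfb, dfw = _anova_f(np.asarray(residuals, dtype=float), np.asarray(study))
    return pd.DataFrame({"F": F, "p": p, "df_between": dfb, "df_within": dfw})


def levene_test(
    residuals: np.ndarray, study: np.ndarray, center: str = "mean"
) -> pd.DataFrame:
    """Per-parcel Levene test: ANOVA on absolute deviations from the group center.

    ``center='mean'`` is the classic Levene statistic; ``'median'`` gives the
    Brown-Forsythe variant.
    """
    X = np.asarray(residuals, dtype=float)
    labels = np.asarray(study)
    levels, masks, ns, means = _group_stats(X, labels)
    dev = np.empty_like(X)
    for m in masks:
        if center == "mean":
            c = X[m].mean(axis=0)
        elif center == "median":
            c = np.median(X[m], axis=0)
        else:
            raise ValueError("center must be 'mean' or 'median'")
        dev[m] = np.abs(X[m] - c)
    W, p, dfb, dfw = _anova_f(dev, labels)
    return pd.DataFrame({"W": W, "p": p, "df_between": dfb, "df_within": dfw})


# -- partial R^2 and variance ratios ---------------------------------------

def partial_r2_study(table: FeatureTable, degree: int = 3) -> np.ndarray:
    """Per-parcel partial R^2 for the study factor.

    Compares the covariate model (age polynomial, sex, condition) with and
    without study indicators: (SSE_reduced - SSE_full) / SSE_reduced.
    """
    df = table.data
    spec = DesignSpec(
        age_degree=degree,
        include_sex=df["sex"].nunique() > 1,
        include_condition=df["condition"].nunique() > 1,
    )
    X, _ = covariate_columns(table, spec)
    Y = table.values
    reduced = np.column_stack([np.ones(table.n_records), X])
    studies = list(dict.fromkeys(df["study"]))
    dummies = np.column_stack(
        [(df["study"] == b).to_numpy(dtype=float) for b in studies[1:]]
    ) if len(studies) > 1 else np.empty((len(df), 0))
    full = np.column_stack([reduced, dummies])

    def sse(D):
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        return ((Y - D @ coef) ** 2).sum(axis=0)

    sse_red = sse(reduced)
    sse_full = sse(full)
    out = np.zeros(table.n_parcels)
    nz = sse_red > 0
    if (~nz).any():
        warnings.warn("zero reduced-model SSE; partial R^2 set to 0", UserWarning)
    out[nz] = (sse_red[nz] - sse_full[nz]) / sse_red[nz]
    return np.clip(out, 0.0, 1.0)


def mean_abs_log_vr(residuals: np.ndarray, study: np.ndarray) -> np.ndarray:
    """Per parcel: mean over studies of |ln(study residual variance / pooled)|.

    Variances use n-1 denominators; the pooled variance is computed on the
    concatenated residual vector.
    """
    X = np.asarray(residuals, dtype=float)
    labels = np.asarray(study)
    levels = list(dict.fromkeys(labels))
    pooled = X.var(axis=0, ddof=1)
    if (pooled <= 0).any():
        raise ValueError("zero pooled residual variance")
    acc = np.zeros(X.shape[1])
    for b in levels:
        v = X[labels == b].var(axis=0, ddof=1)
        if (v <= 0).any():
            raise ValueError(f"zero residual variance in study {b!r}")
        acc += np.abs(np.log(v / pooled))
    return acc / len(levels)


# -- condition-effect t-tests ----------------------------------------------

def condition_effect_tests(
    table: FeatureTable,
    rois: tuple[str, ...] = OCCIPITAL_ROIS,
    mode: str = "paired",
) -> pd.DataFrame:
    """Eyes-open minus eyes-closed t-tests in the occipital ROIs.

    ``paired``: within-subject differences for subjects recorded in both
    conditions. ``independent``: two-sample pooled-variance t across
    subjects with a single recording each.
    """
    df = table.data
    rois = [r for r in rois if r in table.parcel_names]
    if not rois:
        raise ValueError("none of the requested ROIs are present")
    rows = []
    if mode == "paired":
        eo = df[df["condition"] == "eyes-open"].set_index("subject_id")
        ec = df[df["condition"] == "eyes-closed"].set_index("subject_id")
        common = eo.index.intersection(ec.index)
        if len(common) < 2:
            raise ValueError("paired mode needs subjects recorded in both conditions")
        for roi in rois:
            d = eo.loc[common, roi].to_numpy() - ec.loc[common, roi].to_numpy()
            if np.allclose(d.std(ddof=1), 0.0) and np.allclose(d.mean(), 0.0):
                t, p = 0.0, 1.0  # degenerate all-zero differences
            else:
                t, p = stats.ttest_1samp(d, 0.0)
            rows.append((roi, float(t), float(p), len(common)))
    elif mode == "independent":
        if df.duplicated("subject_id").any():
            raise ValueError("independent mode requires one recording per subject")
        a = df[df["condition"] == "eyes-open"]
        b = df[df["condition"] == "eyes-closed"]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("both conditions need at least 2 recordings")
        for roi in rois:
            t, p = stats.ttest_ind(a[roi], b[roi], equal_var=True)
            rows.append((roi, float(t), float(p), len(a) + len(b)))
    else:
        raise ValueError("mode must be 'paired' or 'independent'")
    return pd.DataFrame(rows, columns=["roi", "t", "p", "n"]).set_index("roi")


# -- age-curve fits ---------------------------------------------------------

def _poly_design(age: np.ndarray, degree: int) -> np.ndarray:
    return np.column_stack([age**d for d in range(degree + 1)])


def poly_age_fit(table: FeatureTable, degree: int = 3) -> np.ndarray:
    """Per-parcel R^2 of an age-polynomial OLS fit to relative power."""
    age = table.data["age"].to_numpy(dtype=float)
    if len(np.unique(age)) < degree + 2:
        raise ValueError(f"need at least {degree + 2} distinct ages")
    D = _poly_design(age, degree)
    Y = table.values
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    sse = ((Y - D @ coef) ** 2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    out = np.zeros(table.n_parcels)
    nz = sst > 0
    out[nz] = 1.0 - sse[nz] / sst[nz]
    return out


def cv_delta_r2(
    table_a: FeatureTable,
    table_b: FeatureTable,
    degree: int = 3,
    k: int = 10,
    repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated k-fold out-of-sample Delta R^2 between two harmonized tables.

    Identical study-stratified fold splits are applied to both tables; per
    fold and parcel the out-of-sample R^2 (about the test-fold mean) of the
    age-polynomial fit is computed, Delta R^2 = R^2_A - R^2_B. Paired
    t-tests over the k * repeats fold values per parcel are BH-FDR
    corrected across parcels.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not table_a.data[["subject_id", "study", "age"]].equals(
        table_b.data[["subject_id", "study", "age"]]
    ):
        raise ValueError("tables must share identical records")
    age = table_a.data["age"].to_numpy(dtype=float)
    labels = table_a.study
    Ya, Yb = table_a.values, table_b.values
    D = _poly_design(age, degree)
    n_parcels = table_a.n_parcels

    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    deltas = []
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seeds[rep]))
        for train, test in splitter.split(D, labels):
            row = np.empty(n_parcels)
            for Y, sign in ((Ya, 1.0), (Yb, -1.0)):
                coef, *_ = np.linalg.lstsq(D[train], Y[train], rcond=None)
                pred = D[test] @ coef
                resid = Y[test] - pred
                sse = (resid**2).sum(axis=0)
                centered = Y[test] - Y[test].mean(axis=0)
                sst = (centered**2).sum(axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
                if sign > 0:
                    row = r2.copy()
                else:
                    row -= r2
            deltas.append(row)
    deltas = np.asarray(deltas)  # folds x parcels

    mean_delta = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    n_folds = deltas.shape[0]
    t = np.zeros(n_parcels)
    p = np.ones(n_parcels)
    nz = sd > 0
    t[nz] = mean_delta[nz] / (sd[nz] / np.sqrt(n_folds))
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), n_folds - 1)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"mean_delta_r2": mean_delta, "t": t, "p": p, "q": q},
        index=table_a.parcel_names if table_a.parcel_names else None,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone and capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- age-binned site maps and concordance ----------------------------------

def age_bin_site_maps(
    table: FeatureTable,
    age_range: tuple[float, float] = (20.0, 30.0),
    min_n: int = 30,
) -> pd.DataFrame:
    """Per-study parcel means over recordings with age in [lo, hi).

    Only studies with at least ``min_n`` qualifying recordings are retained.
    """
    lo, hi = age_range
    df = table.data
    mask = (df["age"] >= lo) & (df["age"] < hi)
    sub = df.loc[mask]
    counts = sub.groupby("study").size()
    keep = counts.index[counts >= min_n]
    if len(keep) == 0:
        raise ValueError(
            f"no study has >= {min_n} recordings in the age range [{lo}, {hi})"
        )
    maps = sub[sub["study"].isin(keep)].groupby("study")[table.parcel_names].mean()
    return maps


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with 1/n moment conventions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    sx2, sy2 = x.var(), y.var()
    return float(2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2))


def icc_3k(maps: np.ndarray, form: str = "consistency") -> float:
    """ICC(3,k): two-way model, average of k raters; parcels are targets.

    ``consistency`` (default) is (MS_targets - MS_error)/MS_targets;
    ``agreement`` additionally penalizes rater mean differences.
    """
    X = np.asarray(maps, dtype=float).T  # targets (parcels) x raters (studies)
    n, k = X.shape
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "consistency":
        return float((msr - mse) / msr)
    if form == "agreement":
        return float((msr - mse) / (msr + (msc - mse) / n))
    raise ValueError("form must be 'consistency' or 'agreement'")


def concordance_report(maps: pd.DataFrame, icc_form: str = "consistency") -> dict:
    """Median pairwise Pearson r and CCC, ICC(3,k), median parcel CV."""
    X = maps.to_numpy(dtype=float)
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 study maps")
    pearsons, cccs = [], []
    for i in range(m):
        for j in range(i + 1, m):
            if X[i].std() == 0 or X[j].std() == 0:
                warnings.warn("zero-variance map; pair dropped", UserWarning)
                continue
            pearsons.append(float(np.corrcoef(X[i], X[j])[0, 1]))
            cccs.append(lin_ccc(X[i], X[j]))
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    ok = np.abs(means) > 1e-12
    if (~ok).any():
        warnings.warn("near-zero parcel means; CV entries dropped", UserWarning)
    cv = sds[ok] / np.abs(means[ok])
    return {
        "median_pearson": float(np.median(pearsons)),
        "median_ccc": float(np.median(cccs)),
        "icc_3k": icc_3k(X, form=icc_form),
        "median_cv": float(np.median(cv)),
        "n_studies": m,
    }


# -- combined report --------------------------------------------------------

def evaluation_report(
    table: FeatureTable,
    degree: int = 3,
    rois: tuple[str, ...] = OCCIPITAL_ROIS,
    age_bin: tuple[float, float] = (20.0, 30.0),
    min_n: int = 30,
) -> dict:
    """Full per-parcel diagnostic battery plus summary scalars for one table."""
    resid = residualize(table, degree=degree)
    anova = study_anova(resid, table.study)
    levene = levene_test(resid, table.study)
    pr2 = partial_r2_study(table, degree=degree)
    logvr = mean_abs_log_vr(resid, table.study)
    r2_quad = poly_age_fit(table, degree=2)
    r2_cubic = poly_age_fit(table, degree=degree)
    report = {
        "anova_F": anova["F"].tolist(),
        "anova_p": anova["p"].tolist(),
        "levene_W": levene["W"].tolist(),
        "levene_p": levene["p"].tolist(),
        "partial_r2": pr2.tolist(),
        "mean_abs_log_vr": logvr.tolist(),
        "r2_quadratic": r2_quad.tolist(),
        "r2_cubic": r2_cubic.tolist(),
        "summary": {
            "median_partial_r2": float(np.median(pr2)),
            "median_mean_abs_log_vr": float(np.median(logvr)),
            "mean_anova_F": float(anova["F"].mean()),
            "mean_levene_W": float(levene["W"].mean()),
            "max_r2_cubic": float(r2_cubic.max()),
            "mean_r2_cubic": float(r2_cubic.mean()),
        },
    }
    try:
        ind = condition_effect_tests(table, rois, mode="independent")
        report["independent_t"] = ind["t"].to_dict()
    except ValueError:
        report["independent_t"] = None
    try:
        maps = age_bin_site_maps(table, age_bin, min_n)
        report["concordance"] = concordance_report(maps)
    except ValueError:
        report["concordance"] = None
    return report
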