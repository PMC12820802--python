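"""Synthetic multi-study spectral-power generator with known ground truth.

The generator emits recordings-by-parcels tables from the same generative
structure the location/scale harmonizers assume:

    y_ijv = alpha_v + f_v(age) + b_sex*sex + b_cond*cond + gamma_iv + delta_iv * eps_ijv

with additive study effects gamma_iv ~ Normal(gamma_i, tau_i^2), multiplicative
study effects delta_iv^2 ~ InverseGamma(lambda_i, theta_i) and Gaussian noise
eps_ijv ~ N(0, sigma_v^2). Study profiles emulate the demographic heterogeneity
of a 16-study MEG consortium: a few large lifespan studies, several narrow
young-adult studies, one adolescent study, and mixed eyes-open/eyes-closed
condition policies.

Randomness is a single root seed split per study through
``numpy.random.SeedSequence.spawn`` (study k uses child k, in profile order),
so per-study draws are independent and the noise field is unchanged when only
the effect sizes change. Within each study stream the draw order is fixed:
noise first, then additive effects, then multiplicative effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    DK_PARCELS,
    OCCIPITAL_ROIS,
    COVARIATE_COLUMNS,
    FeatureTable,
)


@dataclass(frozen=True)
class StudyProfile:
    """Demographics of one synthetic study."""

    study: str
    n_subjects: int
    age_range: tuple[float, float]
    age_shape: str = "uniform"  # 'uniform' or 'lifespan' (truncated normal)
    sex_fraction: float = 0.5  # fraction male
    condition_policy: str = "EC-only"  # 'EC-only', 'EO-only', 'both'

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"{self.study}: age range must satisfy min < max")
        if self.n_subjects < 2:
            raise ValueError(f"{self.study}: n_subjects must be >= 2")
        if not 0.0 <= self.sex_fraction <= 1.0:
            raise ValueError(f"{self.study}: sex_fraction must lie in [0, 1]")
        if self.age_shape not in ("uniform", "lifespan"):
            raise ValueError(f"{self.study}: unknown age_shape {self.age_shape!r}")
        if self.condition_policy not in ("EC-only", "EO-only", "both"):
            raise ValueError(f"{self.study}: unknown condition_policy")


@dataclass
class EffectSpec:
    """Ground-truth effect sizes for :func:`simulate_power`.

    Per-parcel pieces are vectors over ``parcel_names``; per-study
    hyperparameters are keyed by study label. ``delta_hyper=None`` fixes all
    multiplicative effects at 1; ``gamma_hyper=None`` fixes additive effects
    at 0 (the no-site-effect regime).
    """

    parcel_names: list[str]
    alpha: np.ndarray                       # per-parcel intercepts
    age_coef: np.ndarray                    # parcels x 3 cubic coefficients in t=(age-45)/45
    sex_effect: np.ndarray                  # per-parcel additive effect of male
    condition_effect: np.ndarray            # per-parcel effect of eyes-open (negative: EC > EO)
    noise_sd: np.ndarray                    # per-parcel sigma_v
    gamma_hyper: dict[str, tuple[float, float]] | None = None   # study -> (gamma_i, tau_i)
    delta_hyper: dict[str, tuple[float, float]] | None = None   # study -> (lambda_i, theta_i)
    clamp_margin: float = 1e-4
    heavy_tailed: bool = False  # model-violating mode: t(3) site effects and noise

    def __post_init__(self) -> None:
        v = len(self.parcel_names)
        for name in ("alpha", "sex_effect", "condition_effect", "noise_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (v,):
                raise ValueError(f"{name} must have length {v}, got shape {arr.shape}")
            setattr(self, name, arr)
        self.age_coef = np.asarray(self.age_coef, dtype=float)
        if self.age_coef.shape != (v, 3):
            raise ValueError(f"age_coef must have shape ({v}, 3)")
        if (self.noise_sd <= 0).any():
            raise ValueError("noise_sd must be positive")

    def without_site_effects(self) -> "EffectSpec":
        """Copy with gamma = 0 and delta = 1 (ground-truth regime)."""
        out = EffectSpec(
            parcel_names=list(self.parcel_names),
            alpha=self.alpha.copy(),
            age_coef=self.age_coef.copy(),
            sex_effect=self.sex_effect.copy(),
            condition_effect=self.condition_effect.copy(),
            noise_sd=self.noise_sd.copy(),
            gamma_hyper=None,
            delta_hyper=None,
            clamp_margin=self.clamp_margin,
            heavy_tailed=self.heavy_tailed,
        )
        return out

    def mean_surface(self, covariates: pd.DataFrame) -> np.ndarray:
        """Noise-free mean for each record: alpha_v + f_v(age) + sex + condition."""
        t = (covariates["age"].to_numpy(dtype=float) - 45.0) / 45.0
        T = np.column_stack([t, t**2, t**3])  # n x 3
        sex = (covariates["sex"] == "M").to_numpy(dtype=float)
        cond = (covariates["condition"] == "eyes-open").to_numpy(dtype=float)
        return (
            self.alpha[None, :]
            + T @ self.age_coef.T
            + sex[:, None] * self.sex_effect[None, :]
            + cond[:, None] * self.condition_effect[None, :]
        )


@dataclass
class SyntheticTruth:
    """Realized effects and noise-free surface for recovery tests."""

    gamma: pd.DataFrame          # studies x parcels realized gamma_iv
    delta2: pd.DataFrame         # studies x parcels realized delta_iv^2
    mean_surface: np.ndarray     # records x parcels, noise-free
    seed: int
    n_clamped: int = 0
    clamp_fraction: float = 0.0


# -- roster sampling -------------------------------------------------------

def sample_roster(profiles: list[StudyProfile], seed: int) -> FeatureTable:
    """Draw covariates (no parcel values) for every profile; deterministic per seed."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    frames = []
    for profile, child in zip(profiles, children):
        rng = np.random.default_rng(child)
        lo, hi = profile.age_range
        n = profile.n_subjects
        if profile.age_shape == "lifespan":
            mu, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
            a, b = (lo - mu) / sd, (hi - mu) / sd
            ages = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
        else:
            ages = rng.uniform(lo, hi, size=n)
        sex = np.where(rng.random(n) < profile.sex_fraction, "M", "F")
        rows = []
        for k in range(n):
            sid = f"{profile.study}_s{k:04d}"
            if profile.condition_policy == "both":
                conds = ["eyes-closed", "eyes-open"]
            elif profile.condition_policy == "EO-only":
                conds = ["eyes-open"]
            else:
                conds = ["eyes-closed"]
            for c in conds:
                rows.append((sid, profile.study, ages[k], sex[k], c))
        frames.append(pd.DataFrame(rows, columns=list(COVARIATE_COLUMNS)))
    data = pd.concat(frames, ignore_index=True)
    return FeatureTable(data, band="alpha", parcel_names=[])


# -- power simulation ------------------------------------------------------

def simulate_power(
    roster: FeatureTable,
    effects: EffectSpec,
    seed: int,
    band: str = "delta",
    noise_corr: dict[str, float] | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Fill a roster with simulated relative power; returns table plus truth.

    ``noise_corr`` optionally gives a within-study equicorrelation of the
    noise across parcels (used to emulate study-specific residual
    covariance); omitted studies get independent noise.
    """
    cov = roster.covariates
    studies = list(dict.fromkeys(cov["study"]))  # first-appearance order
    v = len(effects.parcel_names)
    mean = effects.mean_surface(cov)
    if mean.shape[1] != v:
        raise ValueError("effect vectors inconsistent with parcel count")

    values = np.empty((len(cov), v))
    gamma = np.zeros((len(studies), v))
    delta2 = np.ones((len(studies), v))
    children = np.random.SeedSequence(seed).spawn(len(studies))
    study_arr = cov["study"].to_numpy()
    for i, (study, child) in enumerate(zip(studies, children)):
        rng = np.random.default_rng(child)
        mask = study_arr == study
        n_i = int(mask.sum())
        # draw order fixed: noise, additive base, multiplicative
        if effects.heavy_tailed:
            eps = rng.standard_t(3, size=(n_i, v)) / np.sqrt(3.0)
        else:
            eps = rng.standard_normal((n_i, v))
        if noise_corr and study in noise_corr:
            rho = noise_corr[study]
            shared = rng.standard_normal((n_i, 1))
            eps = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        gbase = rng.standard_normal(v)
        if effects.gamma_hyper is not None:
            g_mean, g_tau = effects.gamma_hyper[study]
            gamma[i] = g_mean + g_tau * gbase
        if effects.delta_hyper is not None:
            lam, theta = effects.delta_hyper[study]
            delta2[i] = theta / rng.gamma(lam, size=v)
        values[mask] = (
            mean[mask]
            + gamma[i][None, :]
            + np.sqrt(delta2[i])[None, :] * effects.noise_sd[None, :] * eps
        )

    m = effects.clamp_margin
    n_clamped = int(((values < m) | (values > 1.0 - m)).sum())
    values = np.clip(values, m, 1.0 - m)

    data = cov.copy()
    for j, name in enumerate(effects.parcel_names):
        data[name] = values[:, j]
    table = FeatureTable(data, band=band, parcel_names=list(effects.parcel_names))
    truth = SyntheticTruth(
        gamma=pd.DataFrame(gamma, index=studies, columns=effects.parcel_names),
        delta2=pd.DataFrame(delta2, index=studies, columns=effects.parcel_names),
        mean_surface=mean,
        seed=seed,
        n_clamped=n_clamped,
        clamp_fraction=n_clamped / values.size,
    )
    return table, truth


# -- default study conditions ---------------------------------------------

def consortium_profiles() -> list[StudyProfile]:
    """Sixteen fixed profiles emulating a heterogeneous MEG consortium.

    Several lifespan studies (one very large), a cluster of narrow
    young-adult studies, one adolescent study, and six studies recording
    both conditions (enabling paired eyes-open/eyes-closed contrasts).
    """
    return [
        StudyProfile("camcan", 600, (18, 88), "lifespan", 0.49, "EC-only"),
        StudyProfile("hcp", 89, (22, 35), "uniform", 0.45, "EO-only"),
        StudyProfile("mous", 200, (18, 45), "uniform", 0.48, "EO-only"),
        StudyProfile("omega", 120, (18, 70), "lifespan", 0.55, "EC-only"),
        StudyProfile("nimh_rv", 100, (18, 65), "lifespan", 0.40, "both"),
        StudyProfile("natmeg", 60, (40, 80), "uniform", 0.68, "EO-only"),
        StudyProfile("pittsburgh", 150, (30, 85), "lifespan", 0.45, "EC-only"),
        StudyProfile("boystown", 150, (9, 75), "lifespan", 0.52, "EC-only"),
        StudyProfile("nih_anx", 70, (8, 17), "uniform", 0.42, "EC-only"),
        StudyProfile("aston1", 40, (18, 48), "uniform", 0.50, "both"),
        StudyProfile("aston2", 30, (18, 35), "uniform", 0.47, "both"),
        StudyProfile("cambridge", 50, (18, 60), "lifespan", 0.50, "EC-only"),
        StudyProfile("cardiff", 90, (18, 55), "uniform", 0.46, "both"),
        StudyProfile("nottingham", 80, (18, 50), "uniform", 0.51, "both"),
        StudyProfile("oxford", 60, (18, 65), "lifespan", 0.53, "both"),
        StudyProfile("rempe", 66, (20, 40), "uniform", 0.50, "EC-only"),
    ]


def default_effects(
    profiles: list[StudyProfile] | None = None,
    parcel_names: list[str] | None = None,
    gamma_sd: float = 0.05,
    delta_mean: float = 1.5,
    site_effects: bool = True,
) -> EffectSpec:
    """Deterministic default effect sizes on the (0, 1) relative-power scale.

    Additive study effects have overall standard deviation ``gamma_sd``
    (split evenly between a between-study mean shift and within-study
    across-parcel spread); multiplicative effects are inverse-gamma with
    mean ``delta_mean``. The cubic age surface declines over the lifespan
    with a clear maximum-effect parcel, the occipital ROIs carry an
    eyes-closed > eyes-open contrast, and the noise scale is chosen so that
    raw-data cubic age fits in the most affected parcel explain roughly half
    the variance.
    """
    if profiles is None:
        profiles = consortium_profiles()
    if parcel_names is None:
        parcel_names = list(DK_PARCELS)
    v = len(parcel_names)
    idx = np.arange(v)

    alpha = 0.25 + 0.08 * np.sin(2.0 * np.pi * idx / max(v, 1))
    # cubic shape in t = (age-45)/45: monotone-ish decline with curvature
    shape = np.array([-0.55, -0.15, 0.35])
    weight = 0.3 + 0.7 * np.exp(-((idx - v // 3) ** 2) / (2.0 * (v / 5.0) ** 2))
    age_coef = 0.11 * weight[:, None] * shape[None, :]

    sex_effect = np.full(v, 0.008)
    condition_effect = np.zeros(v)
    for j, name in enumerate(parcel_names):
        if name in OCCIPITAL_ROIS:
            condition_effect[j] = -0.02  # eyes-open lower: EC > EO
    noise_sd = np.full(v, 0.018)

    gamma_hyper = delta_hyper = None
    if site_effects:
        comp = gamma_sd / np.sqrt(2.0)
        m = len(profiles)
        # deterministic, zero-mean spread of study-level means
        z = stats.norm.ppf((np.arange(m) + 0.5) / m)
        z = (z - z.mean()) / z.std()
        gamma_hyper = {
            p.study: (comp * z[i], comp) for i, p in enumerate(profiles)
        }
        lam = 21.0
        theta = delta_mean * (lam - 1.0)
        delta_hyper = {p.study: (lam, theta) for p in profiles}

    return EffectSpec(
        parcel_names=list(parcel_names),
        alpha=alpha,
        age_coef=age_coef,
        sex_effect=sex_effect,
        condition_effect=condition_effect,
        noise_sd=noise_sd,
        gamma_hyper=gamma_hyper,
        delta_hyper=delta_hyper,
    )
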