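import numpy as np
import pandas as pd
import pytest

from megharm.core_data import FeatureTable
from megharm.synthetic import (
    StudyProfile,
    default_effects,
    sample_roster,
    simulate_power,
)


def make_table(
    values,
    study,
    age=None,
    sex=None,
    condition=None,
    parcel_names=None,
    band="alpha",
    subject_id=None,
):
    """Assemble a FeatureTable from plain arrays (test helper)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, v = values.shape
    study = np.asarray(study)
    if age is None:
        age = np.linspace(20, 60, n)
    if sex is None:
        sex = np.where(np.arange(n) % 2 == 0, "F", "M")
    if condition is None:
        # offset pattern so sex and condition stay linearly independent
        condition = np.where(np.arange(n) % 3 == 0, "eyes-closed", "eyes-open")
    if parcel_names is None:
        parcel_names = [f"p{j}" for j in range(v)]
    if subject_id is None:
        subject_id = [f"sub{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "study": study,
            "age": np.asarray(age, dtype=float),
            "sex": sex,
            "condition": condition,
        }
    )
    for j, name in enumerate(parcel_names):
        df[name] = values[:, j]
    return FeatureTable(df, band, list(parcel_names))


@pytest.fixture
def toy_two_batch():
    """The hand-computable two-batch instance: values {0,2} and {10,12}."""
    return make_table(
        [[0.0], [2.0], [10.0], [12.0]],
        study=["s1", "s1", "s2", "s2"],
        age=[30, 40, 35, 45],
        sex=["F", "M", "F", "M"],
        condition=["eyes-closed"] * 4,
    )


def small_profiles(n_per=80, n_studies=6):
    policies = ["both", "EC-only", "EO-only"]
    return [
        StudyProfile(
            f"st{i:02d}",
            n_per,
            (18, 85) if i % 2 else (20, 45),
            "lifespan" if i % 2 else "uniform",
            0.5,
            policies[i % 3],
        )
        for i in range(n_studies)
    ]


@pytest.fixture(scope="session")
def synthetic_small():
    """Six-study table with default-scale site effects (session-cached)."""
    profiles = small_profiles()
    effects = default_effects(profiles, parcel_names=[f"p{j}" for j in range(20)])
    roster = sample_roster(profiles, seed=51)
    table, truth = simulate_power(roster, effects, seed=52)
    return table, truth, effects
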