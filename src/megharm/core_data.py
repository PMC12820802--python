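"""Data model, table I/O, subject deduplication, and design matrices.

A :class:`FeatureTable` is the common currency of the package: one row per
MEG recording, covariate columns (``subject_id``, ``study``, ``age``,
``sex``, ``condition``) and one column per cortical parcel holding relative
spectral power for a single frequency band. Tables live on disk as
tab-delimited UTF-8 text so fixtures stay human-inspectable and diff-able.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BANDS = ("delta", "theta", "alpha", "beta", "gamma")

CONDITION_LEVELS = ("eyes-closed", "eyes-open")
SEX_LEVELS = ("F", "M")

COVARIATE_COLUMNS = ("subject_id", "study", "age", "sex", "condition")

# Desikan-Killiany atlas: 34 cortical regions per hemisphere.
_DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "temporalpole", "transversetemporal",
)

DK_PARCELS = tuple(f"{r}-{h}" for h in ("lh", "rh") for r in _DK_REGIONS)

OCCIPITAL_ROIS = (
    "pericalcarine-lh", "pericalcarine-rh",
    "lateraloccipital-lh", "lateraloccipital-rh",
)


class SchemaError(ValueError):
    """A table is missing required columns or violates the schema."""


class ValidationError(ValueError):
    """A table has structurally valid columns but invalid content."""


@dataclass
class FeatureTable:
    """Recordings x parcels relative-power matrix joined to covariates.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per recording. Must contain the five covariate columns and
        one numeric column per parcel, in ``parcel_names`` order.
    band : str
        One of ``delta, theta, alpha, beta, gamma``.
    parcel_names : list of str
        Parcel column labels (DK labels with hemisphere suffix for real-shaped
        tables; toys may use any labels).
    """

    data: pd.DataFrame
    band: str = "alpha"
    parcel_names: list[str] = field(default_factory=lambda: list(DK_PARCELS))

    def __post_init__(self) -> None:
        self.parcel_names = list(self.parcel_names)
        # range check is enforced at file-reading time; harmonized values may
        # legitimately leave [0, 1] by a small margin
        self.validate(power_range="ignore")

    # -- accessors ---------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_names)

    @property
    def values(self) -> np.ndarray:
        """Recordings x parcels power matrix as float ndarray."""
        return self.data[self.parcel_names].to_numpy(dtype=float)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[list(COVARIATE_COLUMNS)]

    @property
    def study(self) -> np.ndarray:
        return self.data["study"].to_numpy()

    def with_values(self, values: np.ndarray, band: str | None = None) -> "FeatureTable":
        """Return a copy with the power matrix replaced (covariates shared)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_records, self.n_parcels):
            raise ValueError(
                f"replacement values have shape {values.shape}, expected "
                f"{(self.n_records, self.n_parcels)}"
            )
        data = self.data.copy()
        data[self.parcel_names] = values
        return FeatureTable(data, band or self.band, self.parcel_names)

    # -- validation --------------------------------------------------------
    def validate(self, power_range: str = "warn") -> None:
        """Check schema and invariants.

        power_range : {'warn', 'error', 'ignore'}
            How to treat power values outside [0, 1].
        """
        if self.band not in BANDS:
            raise ValidationError(f"unknown band {self.band!r}; expected one of {BANDS}")
        for col in COVARIATE_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"missing required column {col!r}")
        for col in self.parcel_names:
            if col not in self.data.columns:
                raise SchemaError(f"missing parcel column {col!r}")
        if self.n_records == 0:
            return
        age = pd.to_numeric(self.data["age"], errors="coerce")
        if age.isna().any():
            bad = int(np.nonzero(age.isna().to_numpy())[0][0])
            raise ValidationError(f"non-numeric or missing age at row {bad}")
        if (age <= 0).any():
            bad = int(np.nonzero((age <= 0).to_numpy())[0][0])
            raise ValidationError(f"non-positive age at row {bad}")
        bad_cond = ~self.data["condition"].isin(CONDITION_LEVELS)
        if bad_cond.any():
            raise ValidationError(
                f"unknown condition level(s) {sorted(self.data.loc[bad_cond, 'condition'].unique())}"
            )
        bad_sex = ~self.data["sex"].isin(SEX_LEVELS)
        if bad_sex.any():
            raise ValidationError(
                f"unknown sex level(s) {sorted(self.data.loc[bad_sex, 'sex'].unique())}"
            )
        if self.data["sex"].isna().any():
            raise ValidationError("missing sex values")
        vals = self.values
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite parcel value at row {r}, parcel {self.parcel_names[c]!r}"
            )
        if power_range != "ignore" and ((vals < 0) | (vals > 1)).any():
            msg = "parcel power values outside [0, 1] encountered"
            if power_range == "error":
                raise ValidationError(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
        dup = self.data.duplicated(subset=["subject_id", "condition"])
        if dup.any():
            subjects = sorted(self.data.loc[dup, "subject_id"].unique())
            raise ValidationError(
                f"duplicate (subject_id, condition) pairs for subjects {subjects}"
            )


# -- table I/O -------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> str:
    """Write a table as tab-delimited text; deterministic column order."""
    cols = list(COVARIATE_COLUMNS) + list(table.parcel_names)
    df = table.data[cols]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
    return str(path)


def read_feature_table(path, band: str, power_range: str = "warn") -> FeatureTable:
    """Read a tab-delimited feature table written by :func:`write_feature_table`.

    Every non-covariate column in the file is taken as a parcel column, in
    file order. Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (with the row index) for unparseable content.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "study": str})
    for col in COVARIATE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    parcels = [c for c in df.columns if c not in COVARIATE_COLUMNS]
    for col in parcels:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValidationError(f"non-numeric value in parcel {col!r} at row {row}")
        df[col] = coerced
    table = FeatureTable.__new__(FeatureTable)
    table.data = df
    table.band = band
    table.parcel_names = parcels
    table.validate(power_range=power_range)
    return table


# -- deduplication ---------------------------------------------------------

def select_one_recording_per_subject(
    table: FeatureTable, preferred: str = "eyes-closed"
) -> FeatureTable:
    """Keep exactly one recording per subject.

    When a subject has recordings in both conditions, the ``preferred``
    condition is kept; subjects with a single recording pass through
    unchanged. Row order of the kept records is preserved.
    """
    if preferred not in CONDITION_LEVELS:
        raise ValueError(f"preferred condition must be one of {CONDITION_LEVELS}")
    df = table.data
    counts = df.groupby("subject_id")["condition"].nunique()
    n_rec = df.groupby("subject_id").size()
    if (n_rec > counts).any():
        dups = sorted(n_rec.index[n_rec > counts])
        raise ValidationError(f"duplicate (subject, condition) pairs for {dups}")
    dual = set(counts.index[counts == 2])
    keep = ~(df["subject_id"].isin(dual) & (df["condition"] != preferred))
    out = df.loc[keep].reset_index(drop=True)
    return FeatureTable(out, table.band, table.parcel_names)


# -- design matrices -------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Covariate design: polynomial age degree or a smooth-age flag.

    ``age_degree`` in {1, 2, 3} for raw polynomial terms; ``smooth_age=True``
    requests a spline representation (mutually exclusive with degree > 1).
    """

    age_degree: int = 1
    smooth_age: bool = False
    include_age: bool = True
    include_sex: bool = True
    include_condition: bool = True

    def __post_init__(self) -> None:
        if self.age_degree not in (1, 2, 3):
            raise ValueError("age_degree must be 1, 2 or 3")
        if self.smooth_age and self.age_degree > 1:
            raise ValueError("smooth_age is mutually exclusive with age_degree > 1")


@dataclass
class DesignMatrix:
    values: np.ndarray  # records x p, first column all ones
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("design shape / column-name mismatch")
        if self.values.shape[0] and not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first design column must be the intercept")


def covariate_columns(table: FeatureTable, spec: DesignSpec, strict: bool = True):
    """Covariate part of the design (no intercept): age terms, sex, condition.

    Sex is coded F=0 / M=1 and condition eyes-closed=0 / eyes-open=1.
    Returns ``(matrix, names)``; matrix has zero columns when the spec
    requests nothing beyond the intercept.
    """
    df = table.data
    cols, names = [], []
    age = df["age"].to_numpy(dtype=float)
    if spec.include_age:
        degree = 1 if spec.smooth_age else spec.age_degree
        for d in range(1, degree + 1):
            cols.append(age**d)
            names.append("age" if d == 1 else f"age^{d}")
    if spec.include_sex:
        sex = (df["sex"] == "M").to_numpy(dtype=float)
        if strict and len(np.unique(sex)) < 2:
            raise ValidationError("sex has a single level; design would be rank deficient")
        cols.append(sex)
        names.append("sex")
    if spec.include_condition:
        cond = (df["condition"] == "eyes-open").to_numpy(dtype=float)
        if strict and len(np.unique(cond)) < 2:
            raise ValidationError(
                "condition has a single level; design would be rank deficient"
            )
        cols.append(cond)
        names.append("condition")
    mat = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return mat, names


def build_design_matrix(table: FeatureTable, spec: DesignSpec) -> DesignMatrix:
    """Intercept + raw age polynomial + 0/1 sex + 0/1 condition, in that order."""
    cov, names = covariate_columns(table, spec)
    values = np.column_stack([np.ones(table.n_records), cov])
    return DesignMatrix(values, ["intercept"] + names)
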