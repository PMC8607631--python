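"""Feature-table assembly: per-recording vectors, triplicate averaging,
and train-statistics standardization.

A :class:`FeatureTable` wraps a pandas DataFrame with five metadata columns
(``subject_id, recording_id, label, sex, age``) followed by named numeric
feature columns. Missing feature values are NaN (empty cells in CSV) and
are excluded from triplicate averages; downstream splits impute
training-set means so no subject is ever dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, SchemaError, TableParseError

METADATA_COLUMNS = ("subject_id", "recording_id", "label", "sex", "age")
VALID_LABELS = ("PD", "healthy")
VALID_SEX = ("male", "female")
POSITIVE_LABEL = "PD"
SEX_CODES = {"male": 0.0, "female": 1.0}


@dataclass
class FeatureTable:
    """Rows of (subject, recording, label, sex, age, named features)."""

    df: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.feature_names = list(self.feature_names)
        missing = [c for c in METADATA_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        unknown = [
            c
            for c in self.df.columns
            if c not in METADATA_COLUMNS and c not in self.feature_names
        ]
        if unknown:
            raise SchemaError(f"unknown columns: {unknown}")
        absent = [c for c in self.feature_names if c not in self.df.columns]
        if absent:
            raise SchemaError(f"feature columns absent from table: {absent}")
        self.df = self.df.reset_index(drop=True)
        key = self.df[["subject_id", "recording_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise TableParseError(f"duplicated (subject_id, recording_id): {dup}")
        bad_label = ~self.df["label"].isin(VALID_LABELS)
        if bad_label.any():
            raise SchemaError(
                f"invalid label at row {int(np.flatnonzero(bad_label)[0])}"
            )
        for col in ("label", "sex"):
            per_subject = self.df.groupby("subject_id")[col].nunique()
            if (per_subject > 1).any():
                subject = per_subject[per_subject > 1].index[0]
                raise ConsistencyError(
                    f"subject {subject!r} has conflicting {col} values"
                )
        for name in self.feature_names:
            self.df[name] = pd.to_numeric(self.df[name])

    # -- accessors ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        """Feature matrix (rows x features), NaN for missing."""
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary labels, PD (positive class) = 1."""
        return (self.df["label"] == POSITIVE_LABEL).to_numpy(dtype=int)

    def subset_features(self, names) -> "FeatureTable":
        names = list(names)
        absent = [n for n in names if n not in self.feature_names]
        if absent:
            raise SchemaError(f"table lacks selected features: {absent}")
        cols = list(METADATA_COLUMNS) + names
        return FeatureTable(self.df[cols].copy(), feature_names=names)

    def with_sex_feature(self, name: str = "sex_code") -> "FeatureTable":
        """Prepend the binary sex indicator (male=0, female=1) as a feature."""
        df = self.df.copy()
        df[name] = self.df["sex"].map(SEX_CODES)
        return FeatureTable(df, feature_names=[name] + self.feature_names)

    # -- operations --------------------------------------------------------

    def aggregate_by_subject(self) -> "FeatureTable":
        """Average each subject's recordings component-wise into one row.

        Missing values are excluded from each mean; the aggregated
        recording_id is "mean". Idempotent on already-aggregated tables.
        """
        rows = []
        for subject, grp in self.df.groupby("subject_id", sort=True):
            row = {
                "subject_id": subject,
                "recording_id": "mean",
                "label": grp["label"].iloc[0],
                "sex": grp["sex"].iloc[0],
                "age": grp["age"].iloc[0],
            }
            for name in self.feature_names:
                row[name] = grp[name].mean(skipna=True)
            rows.append(row)
        return FeatureTable(
            pd.DataFrame(rows), feature_names=list(self.feature_names)
        )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, dtype={"subject_id": str, "recording_id": str})
        feature_names = [c for c in df.columns if c not in METADATA_COLUMNS]
        for name in feature_names:
            try:
                df[name] = pd.to_numeric(df[name])
            except (ValueError, TypeError) as exc:
                coerced = pd.to_numeric(df[name], errors="coerce")
                bad = int(np.flatnonzero(coerced.isna() & df[name].notna())[0])
                raise TableParseError(
                    f"{path}: non-numeric value in column {name!r} at row {bad}"
                ) from exc
        return cls(df, feature_names=feature_names)

    def to_csv(self, path: str | Path) -> None:
        cols = list(METADATA_COLUMNS) + self.feature_names
        self.df[cols].to_csv(path, index=False)


# read/write aliases matching the operation names used throughout the docs
def read_table(path: str | Path) -> FeatureTable:
    return FeatureTable.from_csv(path)


def write_table(t: FeatureTable, path: str | Path) -> None:
    t.to_csv(path)


@dataclass(frozen=True)
class Scaler:
    """Per-feature training-set mean/sd standardizer.

    Constant columns get sd replaced by 1 so they map to zero rather than
    dividing by zero. Statistics ignore NaN.
    """

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, t: FeatureTable) -> "Scaler":
        if t.n_rows < 2:
            raise SchemaError("scaler needs at least 2 rows to fit")
        x = t.x
        means = np.nanmean(x, axis=0)
        sds = np.nanstd(x, axis=0, ddof=0)
        sds = np.where(sds > 0, sds, 1.0)
        means = np.where(np.isfinite(means), means, 0.0)
        return cls(tuple(t.feature_names), means, sds)

    def transform(self, t: FeatureTable) -> FeatureTable:
        if tuple(t.feature_names) != self.feature_names:
            raise SchemaError("feature names do not match the fitted scaler")
        df = t.df.copy()
        df[list(self.feature_names)] = (t.x - self.means) / self.sds
        return FeatureTable(df, feature_names=list(t.feature_names))


def standardize_fit(t: FeatureTable) -> Scaler:
    return Scaler.fit(t)


def standardize_apply(s: Scaler, t: FeatureTable) -> FeatureTable:
    return s.transform(t)
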