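"""Feature-table preparation for the group factor analysis pipeline.

Turns raw per-subject volumetric measurements (e.g. subcortical structure
volumes) into the standardized matrix the model consumes: optional division
by intracranial volume, pooled centering, and pooled unit-variance scaling.
Also derives group membership proportions from clinical labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "GroupLabels",
    "StandardizationRecord",
    "volume_normalize",
    "standardize",
    "group_proportions",
    "read_cohort_csv",
    "write_cohort_csv",
]


@dataclass
class FeatureMatrix:
    """An N x D table of continuous per-subject features.

    Parameters
    ----------
    values : ndarray of shape (N, D)
        Finite feature values, one row per subject.
    feature_names : list of str
        Unique names for the D features.
    subject_ids : list of str
        Identifiers for the N subjects.
    """

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (subjects x features)")
        n, d = self.values.shape
        if d < 1:
            raise ValueError("at least one feature is required")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(
                f"non-finite entries at (subject, feature) indices {bad[:5].tolist()}"
            )
        self.feature_names = [str(f) for f in self.feature_names]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match number of columns")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature_names must be unique")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupLabels:
    """Per-subject group membership with derived proportions.

    Labels are 1-based group indices in ``{1..M}``; every group must be
    non-empty. ``proportions`` is always recomputed from the labels.
    """

    labels: np.ndarray
    group_names: list[str]
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer array")
        self.group_names = [str(g) for g in self.group_names]
        m = len(self.group_names)
        if m < 1:
            raise ValueError("at least one group is required")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=m) > m:
            raise ValueError(f"labels must lie in 1..{m}")
        counts = np.bincount(self.labels, minlength=m + 1)[1:]
        if np.any(counts == 0):
            empty = [self.group_names[j] for j in np.flatnonzero(counts == 0)]
            raise ValueError(f"groups with no members: {empty}")
        self.proportions = counts / self.labels.size

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_groups + 1)[1:]


@dataclass
class StandardizationRecord:
    """Per-feature mean and standard deviation removed by :func:`standardize`."""

    feature_means: np.ndarray
    feature_sds: np.ndarray

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature_sds must be strictly positive")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.feature_means) / self.feature_sds

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.feature_sds + self.feature_means

    def to_dict(self) -> dict:
        return {
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationRecord":
        return cls(np.asarray(d["feature_means"]), np.asarray(d["feature_sds"]))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StandardizationRecord":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def volume_normalize(volumes: np.ndarray, icv: np.ndarray) -> np.ndarray:
    """Divide each subject's structure volumes by their intracranial volume.

    Converts absolute volumes (e.g. cm^3) into dimensionless volume ratios so
    that head size does not drive the factor structure.
    """
    volumes = np.asarray(volumes, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if icv.ndim != 1 or icv.shape[0] != volumes.shape[0]:
        raise ValueError("icv must be a vector with one entry per subject")
    bad = ~(np.isfinite(icv) & (icv > 0))
    if np.any(bad):
        raise ValueError(
            f"non-positive or missing intracranial volume for subjects at indices "
            f"{np.flatnonzero(bad).tolist()}"
        )
    return volumes / icv[:, None]


def standardize(X: FeatureMatrix) -> tuple[FeatureMatrix, StandardizationRecord]:
    """Center each feature and scale it to unit sample variance.

    Uses the pooled (all-subject) mean and unbiased (N-1 denominator)
    standard deviation. Standardizing pooled, before any group modelling,
    prevents a few large structures from dominating the loadings while
    keeping between-group mean differences in the data.
    """
    means = X.values.mean(axis=0)
    sds = X.values.std(axis=0, ddof=1)
    constant = np.flatnonzero(~(sds > 0))
    if constant.size:
        names = [X.feature_names[i] for i in constant]
        raise ValueError(f"constant feature columns cannot be standardized: {names}")
    record = StandardizationRecord(means, sds)
    out = FeatureMatrix(record.apply(X.values), list(X.feature_names), list(X.subject_ids))
    return out, record


def group_proportions(labels: GroupLabels, percent: bool = False) -> np.ndarray:
    """Observed group membership proportions ``n_j / N``.

    With ``percent=True`` the proportions are returned on the percent scale
    rounded to two decimals, the convention used when reporting cohort
    composition (e.g. 316/70/30 of 416 -> [75.96, 16.83, 7.21]).
    """
    props = labels.proportions
    if percent:
        return np.round(100.0 * props, 2)
    return props.copy()


def read_cohort_csv(
    path,
    label_column: str,
    id_column: str | None = None,
    group_names: list[str] | None = None,
) -> tuple[FeatureMatrix, GroupLabels]:
    """Read a cohort table: one label column, optional id column, numeric features.

    Group labels may be strings or integers; groups are ordered by
    ``group_names`` when given, otherwise by first appearance in the file
    (so that e.g. controls listed first become group 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in [label_column] + ([id_column] if id_column else []) if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns in {path}: {missing}")
    raw_labels = df[label_column].astype(str)
    if group_names is None:
        group_names = list(dict.fromkeys(raw_labels))
    unknown = sorted(set(raw_labels) - set(group_names))
    if unknown:
        raise ValueError(f"labels not in group_names: {unknown}")
    index = {g: j + 1 for j, g in enumerate(group_names)}
    labels = GroupLabels(raw_labels.map(index).to_numpy(), group_names)

    if id_column is not None:
        ids = df[id_column].astype(str).tolist()
    else:
        ids = [f"S{i:05d}" for i in range(len(df))]
    feature_cols = [c for c in df.columns if c not in {label_column, id_column}]
    if not feature_cols:
        raise ValueError("no feature columns found")
    values = df[feature_cols].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return FeatureMatrix(values, feature_cols, ids), labels


def write_cohort_csv(path, X: FeatureMatrix, labels: GroupLabels,
                     id_column: str = "subject_id", label_column: str = "diagnosis") -> None:
    """Write a cohort table in the dialect :func:`read_cohort_csv` accepts."""
    df = pd.DataFrame(X.values, columns=X.feature_names)
    df.insert(0, label_column, [labels.group_names[j - 1] for j in labels.labels])
    df.insert(0, id_column, X.subject_ids)
    df.to_csv(path, index=False)
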