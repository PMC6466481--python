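"""Tabular data model, CSV I/O, normalization, folds, and synthetic cohorts.

Every downstream stage of the pipeline consumes a :class:`FeatureTable`:
a complete (no missing values) numeric matrix for a two-class cohort with
labels coded ``1`` (case, e.g. ischemic-stroke risk) and ``2`` (control).
Records with missing values are rejected outright — the design deliberately
excludes incomplete records rather than imputing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

CASE_LABEL = 1
CONTROL_LABEL = 2


@dataclass(frozen=True)
class FeatureMeta:
    """Per-feature metadata: display name, measurement unit, value kind."""

    name: str
    unit: str = ""
    value_kind: str = "real"  # "integer" | "real"


@dataclass
class FeatureTable:
    """Numeric feature matrix plus binary labels for a two-class cohort.

    Parameters
    ----------
    values : (n_samples, n_features) float array
        Complete numeric matrix; column order is the canonical feature
        order for every downstream vector and matrix.
    labels : (n_samples,) int array
        Class labels in {1, 2}; 1 = case, 2 = control.
    feature_meta : sequence of FeatureMeta
        Ordered per-column metadata; names must be unique.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_meta: list[FeatureMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if not self.feature_meta:
            self.feature_meta = [FeatureMeta(f"f{i}") for i in range(p)]
        if len(self.feature_meta) != p:
            raise ValueError("feature_meta length does not match n_features")
        names = [m.name for m in self.feature_meta]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if n < 4:
            raise ValueError("need at least 4 samples")
        if p < 2:
            raise ValueError("need at least 2 features")
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value at row {i}, column {names[j]!r}; "
                "incomplete records are excluded, not imputed"
            )
        present = set(np.unique(self.labels))
        if present != {CASE_LABEL, CONTROL_LABEL}:
            raise ValueError(
                f"labels must contain exactly the classes {{1, 2}}, got {sorted(present)}"
            )

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.feature_meta]

    def binary_labels(self) -> np.ndarray:
        """Labels re-encoded {case: 1, control: 0} for correlation-style math."""
        return (self.labels == CASE_LABEL).astype(float)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to the given features (in the given order)."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            self.values[:, idx], self.labels.copy(), [self.feature_meta[j] for j in idx]
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_column] = self.labels
        return df


def read_feature_table(path: str | Path, label_column: str = "label") -> FeatureTable:
    """Read a FeatureTable from CSV (header row, comma-separated, '.' decimal).

    The label column is removed from the matrix; remaining columns keep file
    order. Any missing cell, non-numeric feature value, or non-binary label
    raises ``ValueError`` naming the offending cell.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    feat = df.drop(columns=[label_column])
    # locate the first offending cell for a useful message
    for col in feat.columns:
        numeric = pd.to_numeric(feat[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"missing or non-numeric value at row {row}, column {col!r}"
            )
        feat[col] = numeric
    labels = pd.to_numeric(df[label_column], errors="coerce")
    if labels.isna().any():
        row = int(labels.isna().idxmax())
        raise ValueError(f"missing label at row {row}")
    meta = [
        FeatureMeta(
            name=str(col),
            value_kind="integer"
            if np.allclose(feat[col], np.round(feat[col]))
            else "real",
        )
        for col in feat.columns
    ]
    return FeatureTable(feat.to_numpy(dtype=float), labels.to_numpy(dtype=int), meta)


def write_feature_table(
    table: FeatureTable, path: str | Path, label_column: str = "label"
) -> None:
    """Write back as CSV; round-trips exactly through :func:`read_feature_table`."""
    table.to_frame(label_column).to_csv(path, index=False)


def minmax_normalize(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Affine map of a vector onto [0, 1]: (x - min) / (max - min).

    A constant vector maps to all zeros (documented convention: avoids a
    zero division and demotes uninformative features).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def scale_features(values: np.ndarray) -> np.ndarray:
    """Min-max scale every column of a matrix onto [0, 1]."""
    return np.column_stack([minmax_normalize(values[:, j]) for j in range(values.shape[1])])


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified folds.

    Returns an integer array of fold ids in [0, k). Fold sizes differ by at
    most one and per-fold class counts are within one of proportional.
    Deterministic for a given seed.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic two-class cohort with planted signal.

    ``n_informative`` features get class-conditional Gaussian distributions
    whose means differ by ``effect_size`` pooled standard deviations;
    ``n_noise`` features are drawn identically for both classes. Defaults
    emulate a 792-subject, 28-feature clinical cohort with roughly balanced
    classes (398 cases / 394 controls) and a standardized shift of 1.0 on
    the informative features.
    """

    n_samples: int = 792
    n_informative: int = 9
    n_noise: int = 19
    effect_size: float = 1.0
    class_balance: float = 398 / 792
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_noise < 2:
            raise ValueError("need at least 2 features in total")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")


# plausible clinical spans used to dress features in realistic units
_CLINICAL_RANGES = [
    (50.0, 250.0, "IU/L", "integer"),    # enzyme-like
    (0.5, 6.0, "mmol/L", "real"),        # lipid-like
    (40.0, 120.0, "umol/L", "integer"),  # creatinine-like
    (3.0, 9.0, "mmol/L", "real"),        # glucose-like
    (55.0, 85.0, "g/L", "integer"),      # protein-like
]


def generate_synthetic_cohort(spec: SyntheticSpec) -> tuple[FeatureTable, list[str]]:
    """Generate a planted-signal cohort; returns (table, informative names).

    Informative features: N(0, 1) for controls, N(effect_size, 1) for cases,
    then affinely rescaled to a plausible clinical range (affine dressing is
    immaterial downstream since all scorers min-max scale first). Noise
    features are N(0, 1) for everyone. Integer-kind features are rounded.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n1 = int(round(n * spec.class_balance))
    n1 = min(max(n1, 2), n - 2)  # both classes non-trivial
    labels = np.full(n, CONTROL_LABEL)
    labels[:n1] = CASE_LABEL
    rng.shuffle(labels)
    case = labels == CASE_LABEL

    p = spec.n_informative + spec.n_noise
    cols, meta, informative = [], [], []
    for j in range(p):
        z = rng.standard_normal(n)
        if j < spec.n_informative:
            z[case] += spec.effect_size
            name = f"inf_{j + 1:02d}"
            informative.append(name)
        else:
            name = f"noise_{j - spec.n_informative + 1:02d}"
        lo, hi, unit, kind = _CLINICAL_RANGES[j % len(_CLINICAL_RANGES)]
        # map ±3 SD of the latent scale onto the clinical span
        x = lo + (z + 3.0) / 6.0 * (hi - lo)
        if kind == "integer":
            x = np.round(x)
        cols.append(x)
        meta.append(FeatureMeta(name, unit, kind))
    table = FeatureTable(np.column_stack(cols), labels, meta)
    return table, informative
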