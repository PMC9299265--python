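"""Feature-table I/O, preprocessing and the synthetic fixture generator.

The pipeline mirrors a standard tabular biomedical-classification setup:
a CSV with one row per patient, continuous positive features (cell-nucleus
morphology measurements: radius, texture, perimeter, area, ...) and a
diagnosis column with ``M`` (malignant, encoded +1) or ``B`` (benign,
encoded -1).  Preprocessing offers min-max standardization to [0, 1],
a shift-by-one log transform, and one-pass Z-score outlier removal.

Because the original prostate (Kaggle, 100 patients x 8 features) and
breast (UCI WDBC, 569 samples x 30 features) tables are external,
:func:`synth_dataset` generates schema-compatible two-Gaussian fixtures
whose class separation is controlled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import InputError, TableParseError, TransformError

__all__ = [
    "FeatureTable",
    "FoldAssignment",
    "read_feature_table",
    "write_feature_table",
    "encode_labels",
    "minmax_scale",
    "apply_minmax",
    "log_transform",
    "zscore_filter",
    "kfold_split",
    "synth_dataset",
]

LABEL_TO_SIGN = {"M": 1, "B": -1}
SIGN_TO_LABEL = {1: "M", -1: "B"}


@dataclass
class FeatureTable:
    """Samples x features with M/B diagnosis labels and scaling state."""

    ids: np.ndarray
    feature_names: list[str]
    X: np.ndarray
    label_strings: np.ndarray
    y: np.ndarray | None = None  # +/-1 after encode_labels
    scaling: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InputError(f"feature matrix must be 2-D, got shape {self.X.shape}")
        n, d = self.X.shape
        if len(self.ids) != n or len(self.label_strings) != n:
            raise InputError("ids/labels length does not match the feature matrix")
        if len(self.feature_names) != d:
            raise InputError("feature_names length does not match the feature matrix")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def single_class(self) -> bool:
        return len(set(self.label_strings.tolist())) < 2

    def fingerprint(self) -> str:
        """Stable content hash used for fitness caching and run manifests."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(",".join(map(str, self.label_strings)).encode())
        return h.hexdigest()[:16]

    def to_dataframe(self, label_column: str = "Diagnosis") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        df[label_column] = self.label_strings
        return df


def read_feature_table(
    path,
    label_column: str = "Diagnosis",
    id_column: str | None = "id",
) -> FeatureTable:
    """Load a CSV feature table with an M/B label column.

    All non-label, non-id columns are parsed as numeric features; a
    non-numeric cell or an unknown label value raises
    :class:`~genefold.errors.TableParseError` naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise TableParseError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].astype(str).str.strip()
    bad = ~labels.isin(LABEL_TO_SIGN)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableParseError(
            f"row {row}: label {labels.iloc[row]!r} is not 'M' or 'B'"
        )
    feature_cols = [c for c in df.columns if c != label_column and c != id_column]
    feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    if feats.isna().any().any():
        mask = feats.isna().any(axis=1).to_numpy()
        row = int(np.flatnonzero(mask)[0])
        cols = feats.columns[feats.iloc[row].isna()].tolist()
        raise TableParseError(f"row {row}: non-numeric or missing value in {cols}")
    if id_column is not None and id_column in df.columns:
        ids = df[id_column].to_numpy()
    else:
        ids = np.arange(len(df))
    return FeatureTable(
        ids=ids,
        feature_names=feature_cols,
        X=feats.to_numpy(dtype=float),
        label_strings=labels.to_numpy(),
    )


def write_feature_table(table: FeatureTable, path, label_column: str = "Diagnosis") -> None:
    # 17 significant digits round-trip float64 exactly
    table.to_dataframe(label_column).to_csv(path, index=False, float_format="%.17g")


def encode_labels(t: FeatureTable) -> FeatureTable:
    """Map M -> +1 (malignant, positive class) and B -> -1 (benign)."""
    y = np.array([LABEL_TO_SIGN[s] for s in t.label_strings], dtype=int)
    return replace(t, y=y)


def minmax_scale(t: FeatureTable) -> FeatureTable:
    """Min-max standardization of every feature onto [0, 1].

    Per-feature minima/maxima are stored in the scaling state so the same
    transform can be applied to held-out data (:func:`apply_minmax`).
    Constant features map to 0 by convention.
    """
    lo = t.X.min(axis=0)
    hi = t.X.max(axis=0)
    params = {"transform": "minmax", "min": lo.tolist(), "max": hi.tolist()}
    return replace(
        t,
        X=_minmax_apply(t.X, lo, hi),
        scaling=t.scaling + [params],
    )


def apply_minmax(t: FeatureTable, params: dict) -> FeatureTable:
    """Apply previously fitted min-max parameters (leakage-safe path)."""
    lo = np.asarray(params["min"], dtype=float)
    hi = np.asarray(params["max"], dtype=float)
    if lo.shape[0] != t.n_features:
        raise TransformError(
            f"min-max parameters cover {lo.shape[0]} features, table has {t.n_features}"
        )
    return replace(t, X=_minmax_apply(t.X, lo, hi), scaling=t.scaling + [dict(params)])


def _minmax_apply(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    out = (X - lo) / safe
    return np.where(span == 0, 0.0, out)


def log_transform(t: FeatureTable, shift: bool = True) -> FeatureTable:
    """Shift-by-one natural log: ``v -> ln(v + 1)``, total on non-negative data.

    With ``shift=False`` the plain ``ln(v)`` is applied and any non-positive
    value raises.
    """
    if shift:
        if (t.X < 0).any():
            raise TransformError("log_transform with shift requires non-negative features")
        X = np.log1p(t.X)
        kind = "log1p"
    else:
        if (t.X <= 0).any():
            raise TransformError("log_transform without shift requires strictly positive features")
        X = np.log(t.X)
        kind = "log"
    return replace(t, X=X, scaling=t.scaling + [{"transform": kind}])


def zscore_filter(
    t: FeatureTable, threshold: float = 3.0
) -> tuple[FeatureTable, np.ndarray]:
    """Remove samples with ``|z| > threshold`` in *any* feature.

    Z-scores are computed once on the pre-filter table (no iteration);
    constant columns contribute z = 0.  Returns the filtered table and the
    ids of removed samples.
    """
    if t.n_samples < 2:
        raise InputError("zscore_filter needs at least 2 samples")
    if threshold <= 0:
        raise InputError(f"threshold must be positive, got {threshold}")
    mu = t.X.mean(axis=0)
    sd = t.X.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    z = np.abs(t.X - mu) / safe
    z = np.where(sd == 0, 0.0, z)
    keep = ~(z > threshold).any(axis=1)
    removed = t.ids[~keep]
    filtered = replace(
        t,
        ids=t.ids[keep],
        X=t.X[keep],
        label_strings=t.label_strings[keep],
        y=None if t.y is None else t.y[keep],
    )
    return filtered, removed


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified k-fold partition: fold index per sample."""

    fold_index: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)

    def to_csv(self, ids: np.ndarray) -> str:
        lines = ["id,fold"]
        lines += [f"{i},{f}" for i, f in zip(ids, self.fold_index)]
        return "\n".join(lines) + "\n"


def kfold_split(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded stratified k-fold assignment over the given labels."""
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise InputError(f"k must be >= 2, got {k}")
    if k > n:
        raise InputError(f"cannot split {n} samples into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    fold_index = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        fold_index[test] = f
    return FoldAssignment(fold_index=fold_index, k=k, seed=int(seed))


def synth_dataset(
    n: int = 200,
    d: int = 8,
    separation: float = 6.0,
    class_balance: float = 0.5,
    seed: int = 0,
) -> FeatureTable:
    """Two-Gaussian synthetic feature table emulating the cancer datasets.

    Two classes (M/B) of unit-variance Gaussians in ``d`` dimensions whose
    mean vectors sit ``separation`` pooled standard deviations apart along
    the diagonal direction.  Features are shifted to be positive, matching
    the morphology-measurement schema the loader expects.  ``separation=0``
    gives an uninformative null table; ``separation=6`` is essentially
    linearly separable.
    """
    if n < 4 or d < 1:
        raise InputError(f"need n >= 4 and d >= 1, got n={n}, d={d}")
    if not 0 < class_balance < 1:
        raise InputError(f"class_balance must be in (0, 1), got {class_balance}")
    rng = np.random.default_rng(int(seed))
    n_pos = max(1, min(n - 1, int(round(n * class_balance))))
    n_neg = n - n_pos
    direction = np.ones(d) / np.sqrt(d)
    offset = 0.5 * separation * direction
    X = np.concatenate(
        [
            rng.normal(size=(n_pos, d)) + offset,
            rng.normal(size=(n_neg, d)) - offset,
        ]
    )
    labels = np.array(["M"] * n_pos + ["B"] * n_neg)
    perm = rng.permutation(n)
    X, labels = X[perm], labels[perm]
    X = X - X.min(axis=0) + 0.5  # strictly positive features
    return FeatureTable(
        ids=np.arange(n),
        feature_names=[f"feature_{j}" for j in range(d)],
        X=X,
        label_strings=labels,
    )
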