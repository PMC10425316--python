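"""Dataset container, delimited-text I/O, and stratified resampling.

Every stage of the pipeline operates on a dense samples x features table of
continuous biomarker measurements (e.g. plasma/serum protein levels) with a
binary diagnosis label: positive class "ASD" (encoded 1), negative class
"TD" (encoded 0).
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "ASD"
NEGATIVE_LABEL = "TD"
ID_COLUMN = "sample_id"


@dataclasses.dataclass
class Dataset:
    """A labelled biomarker table.

    Attributes
    ----------
    values : (n_samples, n_features) float array of biomarker levels.
    labels : (n_samples,) int array in {0, 1}; 1 is the positive (ASD) class.
    feature_names : one name per column.
    sample_ids : one identifier per row.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_names = list(self.feature_names)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features array")
        n, f = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError(f"labels length {self.labels.shape} != n_samples {n}")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} samples")
        if len(self.feature_names) != f:
            raise ValueError(f"{len(self.feature_names)} feature_names for {f} features")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be encoded 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(positive count, negative count)."""
        pos = int((self.labels == 1).sum())
        return pos, self.n_samples - pos

    def select_features(self, keep: np.ndarray) -> "Dataset":
        keep = np.asarray(keep)
        if keep.dtype == bool and keep.shape != (self.n_features,):
            raise ValueError("feature mask length mismatch")
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return Dataset(
            self.values[:, idx],
            self.labels,
            [self.feature_names[i] for i in idx],
            self.sample_ids,
        )

    def select_samples(self, keep: np.ndarray) -> "Dataset":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return Dataset(
            self.values[idx],
            self.labels[idx],
            self.feature_names,
            [self.sample_ids[i] for i in idx],
        )


@dataclasses.dataclass
class SplitSpec:
    """Proportions for the three-way train/validation/test division.

    The three fractions must sum to 1; `folds` parameterizes k-fold
    cross-validation (default 10 equal groups).
    """

    train_fraction: float = 0.6
    validation_fraction: float = 0.2
    test_fraction: float = 0.2
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def load_dataset(
    path: str | Path,
    label_column: str = "label",
    positive_label: str = POSITIVE_LABEL,
    id_column: str | None = ID_COLUMN,
    sep: str | None = None,
) -> Dataset:
    """Read a delimited biomarker table into a :class:`Dataset`.

    The file must have a header row, one label column with exactly two
    distinct values, and numeric feature columns.  Missing or non-numeric
    cells are a hard error (no imputation), reported by row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=sep if sep is not None else _infer_sep(path),
                     float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")

    raw_labels = df[label_column].astype(str)
    classes = sorted(raw_labels.unique())
    if len(classes) != 2:
        raise ValueError(
            f"label column {label_column!r} must have exactly 2 distinct values, "
            f"found {len(classes)}: {classes}"
        )
    if positive_label in classes:
        pos = positive_label
    else:
        pos = classes[0]  # lexicographically-first value becomes the positive class
        logger.warning(
            "positive label %r not present; using %r as positive class", positive_label, pos
        )
    labels = (raw_labels == pos).astype(int).to_numpy()

    if id_column is not None and id_column in df.columns:
        sample_ids = df[id_column].astype(str).tolist()
        feat = df.drop(columns=[label_column, id_column])
    else:
        sample_ids = [f"S{i:04d}" for i in range(len(df))]
        feat = df.drop(columns=[label_column])

    values = np.empty(feat.shape, dtype=float)
    for j, col in enumerate(feat.columns):
        numeric = pd.to_numeric(feat[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            cell = feat[col].iloc[i]
            kind = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
            raise ValueError(
                f"{kind} value at row {sample_ids[i]!r}, column {col!r}"
            )
        values[:, j] = numeric.to_numpy()

    return Dataset(values, labels, [str(c) for c in feat.columns], sample_ids)


def save_dataset(
    d: Dataset,
    path: str | Path,
    label_column: str = "label",
    sep: str | None = None,
) -> None:
    """Write a Dataset back to delimited text (lossless for finite values)."""
    path = Path(path)
    df = pd.DataFrame(d.values, columns=d.feature_names)
    df.insert(0, label_column, [POSITIVE_LABEL if y else NEGATIVE_LABEL for y in d.labels])
    df.insert(0, ID_COLUMN, d.sample_ids)
    df.to_csv(path, sep=sep if sep is not None else _infer_sep(path), index=False,
              float_format="%.17g")  # 17 significant digits round-trip float64 exactly


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items to parts, within 1 of n*fraction each."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def stratified_split(d: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset, Dataset]:
    """Partition into train/validation/test, stratified by class.

    Class proportions in every part stay within one sample of the global
    proportion; the three index sets are an exact partition; the result is
    deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train_fraction, spec.validation_fraction, spec.test_fraction)
    n_parts = sum(f > 0 for f in fractions)
    parts: list[list[int]] = [[], [], []]
    for cls in (1, 0):
        idx = np.flatnonzero(d.labels == cls)
        if len(idx) < n_parts:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than the {n_parts} "
                "requested non-empty parts"
            )
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fractions)
        start = 0
        for p in range(3):
            parts[p].extend(idx[start : start + counts[p]].tolist())
            start += counts[p]
    out = []
    for p in range(3):
        sel = np.sort(np.asarray(parts[p], dtype=int))
        out.append(d.select_samples(sel))
    return out[0], out[1], out[2]


def kfold(d: Dataset, folds: int = 10, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs (train_idx, test_idx).

    Fold sizes differ by at most one; the test folds partition the index set.
    """
    if folds > d.n_samples:
        raise ValueError(f"folds={folds} exceeds n_samples={d.n_samples}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(d.values, d.labels)]
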