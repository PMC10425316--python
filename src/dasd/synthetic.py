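"""Synthetic biomarker-panel generator with planted ground truth.

Emulates the shape of a blood-protein ASD/TD cohort: a near-balanced
two-class table (default 76 positive / 78 negative = 154 children) with many
continuous protein-level features of which only a small subset carries class
signal, plus a fraction of corrupted or mislabelled training rows.  The
planted masks give the filtering stages (feature selection, outlier
rejection) an exact recovery target.

Model
-----
Informative features are class-conditional Gaussians with unit variance and
a standardized mean gap of ``effect_size`` between classes; noise features
are identically distributed N(0, 1) in both classes.  Outlier rows are
either label-flipped or feature-corrupted: corrupted values are drawn
uniformly from [mu + 6*sigma, mu + 10*sigma] of the clean per-feature
marginal, i.e. far outside the clean range, so recovery is unambiguous.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import Dataset

#: defaults mirror the emulated cohort at desk scale: 154 samples,
#: 50 features of which 15 informative, 10% outliers.
DEFAULT_CLASS_SIZES = (76, 78)


@dataclasses.dataclass
class SyntheticSpec:
    n_samples: int = 154
    class_sizes: tuple[int, int] = DEFAULT_CLASS_SIZES  # (positive, negative)
    n_informative: int = 15
    n_noise: int = 35
    effect_size: float = 2.0
    outlier_rate: float = 0.1
    outlier_mode: str = "feature_corrupt"  # or "label_flip"
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_sizes) != self.n_samples:
            raise ValueError("class_sizes must sum to n_samples")
        if min(self.class_sizes) <= 0 or self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("counts must be positive")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.outlier_mode not in ("feature_corrupt", "label_flip"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_noise


@dataclasses.dataclass
class GroundTruth:
    informative_mask: np.ndarray  # bool per feature
    outlier_mask: np.ndarray  # bool per sample


def generate(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset; bit-identical under a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_samples, spec.n_features
    n_pos, n_neg = spec.class_sizes

    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    rng.shuffle(labels)

    values = rng.standard_normal((n, f))
    informative = np.zeros(f, dtype=bool)
    informative[: spec.n_informative] = True
    # class mean gap = effect_size * sd (sd = 1) on informative columns only
    values[:, informative] += spec.effect_size * labels[:, None]

    # scatter informative columns through the panel
    perm = rng.permutation(f)
    values = values[:, perm]
    informative = informative[perm]

    outlier_mask = np.zeros(n, dtype=bool)
    n_out = int(round(spec.outlier_rate * n))
    if n_out > 0:
        rows = rng.choice(n, size=n_out, replace=False)
        outlier_mask[rows] = True
        if spec.outlier_mode == "label_flip":
            labels[rows] = 1 - labels[rows]
        else:
            clean = np.delete(values, rows, axis=0)
            mu = clean.mean(axis=0)
            sd = clean.std(axis=0)
            lo, hi = mu + 6.0 * sd, mu + 10.0 * sd
            values[rows] = lo + rng.uniform(size=(n_out, f)) * (hi - lo)

    ds = Dataset(
        values,
        labels,
        feature_names=[f"P{j:03d}" for j in range(f)],
        sample_ids=[f"S{i:04d}" for i in range(n)],
    )
    return ds, GroundTruth(informative_mask=informative, outlier_mask=outlier_mask)
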