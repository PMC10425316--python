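"""Naive-Bayes weighting: map samples from feature space to weight space.

The enhanced-KNN classifier does not measure distances on raw biomarker
levels.  A Gaussian Naive-Bayes model is fitted per (class, feature) on the
training split, and each feature value x_f is replaced by its normalized
class-conditional evidence

    w_cf(x) = p_c(x_f) / sum_c' p_c'(x_f)

one coordinate per class, so every sample becomes a vector of length
n_features * n_classes with entries in [0, 1] and the two class coordinates
of each feature summing to 1.  The weight reflects how strongly that
feature value speaks for each class; distances in this space are therefore
evidence distances rather than raw-unit distances.

Features are z-scored with training-split statistics before fitting:
blood-protein levels span orders of magnitude and nearest-neighbour
distances degenerate otherwise.  The z-scaler is stored on the mapping so
queries are transformed identically.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

SIGMA_FLOOR = 1e-6

#: weight-space class order: positive (ASD) coordinate first
CLASS_ORDER = (1, 0)


@dataclasses.dataclass
class WeightMapping:
    """Fitted per-class, per-feature Gaussian NB parameters.

    ``means``/``stds`` have shape (2, n_features), row order ``CLASS_ORDER``;
    ``priors`` are the empirical class frequencies (stored for the NB
    test-oracle predictor; the weight transform itself is prior-free so the
    per-feature coordinates stay symmetric under class imbalance).
    """

    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    priors: np.ndarray

    def __post_init__(self) -> None:
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_std = np.asarray(self.scaler_std, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if (self.stds <= 0).any():
            raise ValueError("class-conditional stds must be positive")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def weight_dim(self) -> int:
        return 2 * self.n_features

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "priors": self.priors.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightMapping":
        return cls(
            feature_names=list(d["feature_names"]),
            scaler_mean=d["scaler_mean"],
            scaler_std=d["scaler_std"],
            means=d["means"],
            stds=d["stds"],
            priors=d["priors"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "WeightMapping":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_weighting(train) -> WeightMapping:
    """Fit the z-scaler and Gaussian NB parameters on a training Dataset.

    Requires at least two samples per class; class-conditional standard
    deviations (and the z-scaler scale) are floored at 1e-6 so constant
    features cannot produce degenerate densities.
    """
    X, y = train.values, train.labels
    counts = [(y == c).sum() for c in CLASS_ORDER]
    for c, n_c in zip(CLASS_ORDER, counts):
        if n_c < 2:
            raise ValueError(f"class {c} has {n_c} training samples; need >= 2")

    scaler_mean = X.mean(axis=0)
    scaler_std = np.maximum(X.std(axis=0), SIGMA_FLOOR)
    Z = (X - scaler_mean) / scaler_std

    means = np.empty((2, X.shape[1]))
    stds = np.empty((2, X.shape[1]))
    for r, c in enumerate(CLASS_ORDER):
        Zc = Z[y == c]
        means[r] = Zc.mean(axis=0)
        stds[r] = np.maximum(Zc.std(axis=0, ddof=1), SIGMA_FLOOR)
    priors = np.asarray(counts, dtype=float) / len(y)

    return WeightMapping(
        feature_names=list(train.feature_names),
        scaler_mean=scaler_mean,
        scaler_std=scaler_std,
        means=means,
        stds=stds,
        priors=priors,
    )


def _class_logdensity(w: WeightMapping, X: np.ndarray) -> np.ndarray:
    """Per-sample, per-class, per-feature Gaussian log density, shape (n, 2, f)."""
    Z = (X - w.scaler_mean) / w.scaler_std
    return norm.logpdf(Z[:, None, :], loc=w.means[None], scale=w.stds[None])


def to_weight_space(w: WeightMapping, x) -> np.ndarray:
    """Transform feature vectors to weight space.

    Accepts a single vector (returns shape ``(2*f,)``) or a matrix of shape
    ``(n, f)`` (returns ``(n, 2*f)``).  Layout is feature-major: coordinates
    ``2*j`` and ``2*j + 1`` are the positive- and negative-class weights of
    feature ``j``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != w.n_features:
        raise ValueError(f"expected {w.n_features} features, got {X.shape[1]}")
    logp = _class_logdensity(w, X)  # (n, 2, f)
    weights = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    out = np.swapaxes(weights, 1, 2).reshape(X.shape[0], -1)  # feature-major
    return out[0] if single else out


def nb_predict(w: WeightMapping, x) -> np.ndarray:
    """Plain Gaussian NB prediction (test oracle; not part of the pipeline)."""
    x = np.asarray(x, dtype=float)
    X = x[None, :] if x.ndim == 1 else x
    logp = _class_logdensity(w, X).sum(axis=2) + np.log(w.priors)[None]
    best = logp.argmax(axis=1)
    labels = np.asarray(CLASS_ORDER)[best]
    return labels if x.ndim > 1 else labels[0]
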