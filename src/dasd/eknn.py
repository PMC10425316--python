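"""Enhanced K-nearest-neighbours (EKNN) classifier.

Fitting proceeds in three stages: (1) fit the Naive-Bayes weighting on the
training split and map it to weight space; (2) run the chimp-optimization
prototype search to generate a small set of per-class New-cases in weight
space; (3) prediction is a K-nearest-neighbour vote (Euclidean, K default
3) of the query's weight-space image over the New-cases.  Because the
prototype set is far smaller than the training data, prediction is fast
without giving up the weighted-KNN decision structure.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coa import COAConfig, PrototypeSet, coa_optimize, knn_predict
from .core_io import Dataset
from .weighting import WeightMapping, fit_weighting, to_weight_space

logger = logging.getLogger(__name__)

DEFAULT_K = 3  # validated best neighbour count on the emulated cohort scale
DEFAULT_CASES_PER_CLASS = 10


@dataclasses.dataclass
class EKNNModel:
    weighting: WeightMapping
    prototypes: PrototypeSet
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.weights.json`` and ``<prefix>.prototypes.csv``."""
        prefix = Path(prefix)
        meta = self.weighting.to_dict()
        meta["k"] = self.k
        Path(f"{prefix}.weights.json").write_text(json.dumps(meta))
        df = pd.DataFrame(
            self.prototypes.cases,
            columns=[f"w{j}" for j in range(self.prototypes.cases.shape[1])],
        )
        df.insert(0, "class", self.prototypes.labels)
        df.to_csv(f"{prefix}.prototypes.csv", index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "EKNNModel":
        prefix = Path(prefix)
        meta = json.loads(Path(f"{prefix}.weights.json").read_text())
        k = meta.pop("k")
        df = pd.read_csv(f"{prefix}.prototypes.csv")
        labels = df.pop("class").to_numpy(dtype=int)
        return cls(
            weighting=WeightMapping.from_dict(meta),
            prototypes=PrototypeSet(cases=df.to_numpy(dtype=float), labels=labels),
            k=k,
        )


def fit_eknn(
    train: Dataset,
    cfg: COAConfig | None = None,
    k: int = DEFAULT_K,
    cases_per_class: int = DEFAULT_CASES_PER_CLASS,
    seed: int = 0,
) -> EKNNModel:
    """Fit weighting + prototype generation on (already filtered) data.

    ``cfg.features_per_case`` must equal the weight-space dimension
    (2 * n_features); pass ``cfg=None`` to build a default configuration
    from the data.  Deterministic under the configuration seed.
    """
    weighting = fit_weighting(train)
    if cfg is None:
        cfg = COAConfig(
            features_per_case=weighting.weight_dim,
            cases_per_class=cases_per_class,
            seed=seed,
            k=k,
        )
    elif cfg.features_per_case != weighting.weight_dim:
        raise ValueError(
            f"cfg.features_per_case={cfg.features_per_case} but weight space "
            f"has dimension {weighting.weight_dim}"
        )
    train_w = to_weight_space(weighting, train.values)
    result = coa_optimize(train_w, train.labels, cfg)
    return EKNNModel(weighting=weighting, prototypes=result.prototypes, k=k)


def predict_eknn(model: EKNNModel, x) -> np.ndarray:
    """Predict labels for a Dataset, a feature matrix, or a single vector."""
    values = x.values if isinstance(x, Dataset) else np.asarray(x, dtype=float)
    single = values.ndim == 1
    W = to_weight_space(model.weighting, values)
    W = np.atleast_2d(W)
    k = min(model.k, model.prototypes.v)
    if k < model.k:
        logger.warning("k=%d exceeds prototype count v=%d; clipping", model.k, model.prototypes.v)
    pred = knn_predict(model.prototypes.cases, model.prototypes.labels, W, k)
    return pred[0] if single else pred


def weighted_knn_predict(train: Dataset, x, k: int = DEFAULT_K) -> np.ndarray:
    """Reduction-free limit of EKNN: KNN over the full weighted training set.

    This is the weighted-KNN hybrid that prototype generation accelerates;
    it doubles as the cheap base classifier for the wrapper filters.
    """
    weighting = fit_weighting(train)
    ref = to_weight_space(weighting, train.values)
    values = x.values if isinstance(x, Dataset) else np.asarray(x, dtype=float)
    W = np.atleast_2d(to_weight_space(weighting, values))
    pred = knn_predict(ref, train.labels, W, min(k, ref.shape[0]))
    return pred[0] if np.asarray(values).ndim == 1 else pred


def weighted_knn_accuracy(train: Dataset, val: Dataset, k: int = DEFAULT_K) -> float:
    """Validation accuracy of the weighted-KNN base classifier."""
    pred = weighted_knn_predict(train, val, k=k)
    return float((pred == val.labels).mean())


def select_k(train: Dataset, val: Dataset, k_range, evaluator=None) -> int:
    """Choose the neighbour count minimizing validation error.

    ``evaluator(train, val, k) -> accuracy`` defaults to the weighted-KNN
    accuracy; ties are broken toward the smallest K.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if evaluator is None:
        evaluator = weighted_knn_accuracy
    best_k, best_err = None, np.inf
    for k in k_range:
        err = 1.0 - evaluator(train, val, k)
        if err < best_err or (err == best_err and best_k is not None and k < best_k):
            best_k, best_err = k, err
    return best_k
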