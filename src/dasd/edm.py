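"""Best-model ensemble (EDM) and the end-to-end diagnostic pipeline.

The ensemble trains its member classifiers on the training split, scores
each on the validation split, and commits to the single member with the
highest validation accuracy (argmax selection; ties resolved by the
declared member order).  The test split is then diagnosed by the winner
only.

Members are thin adapters over a shared fit/predict contract: a
linear-kernel SVM (C = 16), a neural-network adapter (one hidden layer,
learning rate 0.01) standing in the deep-learning slot, a logistic
adapter, and the EKNN classifier.  ``run_dasd`` chains the whole method:
stratified split, BGWO feature filtering, BGA outlier rejection, ensemble
selection, and full metric reporting, with every seed recorded so reruns
are byte-identical.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics
from .bga import BGAConfig, run_bga
from .bgwo import BGWOConfig, run_bgwo
from .coa import COAConfig
from .core_io import Dataset, SplitSpec, stratified_split
from .eknn import DEFAULT_CASES_PER_CLASS, DEFAULT_K, fit_eknn, predict_eknn

logger = logging.getLogger(__name__)

#: declared member order; also the tie-break order of best-model selection
MEMBER_ORDER = ("SVM", "DLA", "EKNN")


@runtime_checkable
class ClassifierContract(Protocol):
    name: str

    def fit(self, train: Dataset) -> "ClassifierContract": ...

    def predict(self, data: Dataset) -> np.ndarray: ...


class _SklearnAdapter:
    """Shared adapter: standardize features, delegate to an estimator."""

    name = "sklearn"

    def __init__(self, estimator):
        self._pipe = make_pipeline(StandardScaler(), estimator)
        self._fitted = False

    def fit(self, train: Dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            self._pipe.fit(train.values, train.labels)
        self._fitted = True
        return self

    def predict(self, data: Dataset) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError(f"{self.name}: predict called before fit")
        return self._pipe.predict(data.values if isinstance(data, Dataset) else data)


class SVMAdapter(_SklearnAdapter):
    """Linear-kernel support vector machine, cost parameter C = 16."""

    name = "SVM"

    def __init__(self, c: float = 16.0):
        super().__init__(SVC(kernel="linear", C=c))


class DLAAdapter(_SklearnAdapter):
    """Neural-network member: one hidden layer, learning rate 0.01.

    A feed-forward multilayer perceptron fills the deep-learning slot of
    the ensemble; width defaults to 64 units.
    """

    name = "DLA"

    def __init__(self, hidden_units: int = 64, learning_rate: float = 0.01, seed: int = 0):
        super().__init__(
            MLPClassifier(
                hidden_layer_sizes=(hidden_units,),
                learning_rate_init=learning_rate,
                max_iter=1000,
                random_state=seed,
            )
        )


class LogisticAdapter(_SklearnAdapter):
    """Always-available lightweight member (logistic regression)."""

    name = "LOGISTIC"

    def __init__(self):
        super().__init__(LogisticRegression(max_iter=1000))


class EKNNClassifier:
    """Contract wrapper around the enhanced-KNN fit/predict functions."""

    name = "EKNN"

    def __init__(self, k: int = DEFAULT_K, cases_per_class: int = DEFAULT_CASES_PER_CLASS,
                 coa_config: COAConfig | None = None, seed: int = 0):
        self.k = k
        self.cases_per_class = cases_per_class
        self.coa_config = coa_config
        self.seed = seed
        self.model = None

    def fit(self, train: Dataset):
        self.model = fit_eknn(
            train,
            cfg=self.coa_config,
            k=self.k,
            cases_per_class=self.cases_per_class,
            seed=self.seed,
        )
        return self

    def predict(self, data: Dataset) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("EKNN: predict called before fit")
        return predict_eknn(self.model, data)


@dataclasses.dataclass
class EDMResult:
    accuracies: dict[str, float]
    best_method: str
    test_predictions: np.ndarray
    test_scores: dict[str, float]
    failures: dict[str, str]


def select_best(acc: dict[str, float], order: tuple[str, ...] | None = None) -> str:
    """Argmax of validation accuracy; ties go to the earliest name in
    ``order`` (default: the map's own insertion order)."""
    if not acc:
        raise ValueError("no member accuracies to select from")
    names = [n for n in (order or acc.keys()) if n in acc]
    names += [n for n in acc if n not in names]
    best = names[0]
    for n in names[1:]:
        if acc[n] > acc[best]:
            best = n
    return best


def run_edm(train: Dataset, val: Dataset, test: Dataset,
            members: list[ClassifierContract]) -> EDMResult:
    """Fit all members, select the validation-accuracy winner, diagnose test.

    A member that raises during fit or validation is excluded with a
    warning; the ensemble proceeds as long as one member remains.
    """
    accuracies: dict[str, float] = {}
    fitted: dict[str, ClassifierContract] = {}
    failures: dict[str, str] = {}
    for m in members:
        try:
            m.fit(train)
            pred = np.asarray(m.predict(val))
            accuracies[m.name] = float((pred == val.labels).mean())
            fitted[m.name] = m
        except Exception as exc:  # noqa: BLE001 - member isolation is the point
            logger.warning("member %s failed and is excluded: %s", m.name, exc)
            failures[m.name] = str(exc)
    if not accuracies:
        raise RuntimeError("every ensemble member failed")

    best = select_best(accuracies, order=tuple(m.name for m in members))
    test_pred = np.asarray(fitted[best].predict(test))
    cm = metrics.confusion(test.labels, test_pred)
    return EDMResult(
        accuracies=accuracies,
        best_method=best,
        test_predictions=test_pred,
        test_scores=metrics.scores(cm),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclasses.dataclass
class DASDConfig:
    """Resolved configuration of one pipeline run.

    Setting ``bgwo``/``bga`` to None disables the corresponding filter.
    """

    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    bgwo: BGWOConfig | None = dataclasses.field(default_factory=BGWOConfig)
    bga: BGAConfig | None = dataclasses.field(default_factory=BGAConfig)
    members: tuple[str, ...] = MEMBER_ORDER
    eknn_k: int = DEFAULT_K
    eknn_cases_per_class: int = DEFAULT_CASES_PER_CLASS
    seed: int = 0

    def __post_init__(self) -> None:
        # propagate the pipeline seed into sub-configs left at their default
        # seed, so `DASDConfig(seed=s)` seeds the whole run coherently
        for sub in (self.split, self.bgwo, self.bga):
            if sub is not None and sub.seed == 0:
                sub.seed = self.seed

    @classmethod
    def from_dict(cls, d: dict) -> "DASDConfig":
        """Build from a JSON-style mapping with optional sections
        {io, bgwo, bga, eknn, edm, seeds}."""
        seeds = d.get("seeds", {})
        base_seed = int(seeds.get("pipeline", d.get("seed", 0)))
        split = SplitSpec(**{**{"seed": base_seed}, **d.get("io", {})})
        bgwo_d = d.get("bgwo", {})
        bgwo = None if bgwo_d is None else BGWOConfig(
            **{**{"seed": int(seeds.get("bgwo", base_seed))}, **bgwo_d})
        bga_d = d.get("bga", {})
        bga = None if bga_d is None else BGAConfig(
            **{**{"seed": int(seeds.get("bga", base_seed))}, **bga_d})
        eknn_d = d.get("eknn", {})
        edm_d = d.get("edm", {})
        return cls(
            split=split,
            bgwo=bgwo,
            bga=bga,
            members=tuple(edm_d.get("members", MEMBER_ORDER)),
            eknn_k=int(eknn_d.get("k", DEFAULT_K)),
            eknn_cases_per_class=int(eknn_d.get("cases_per_class", DEFAULT_CASES_PER_CLASS)),
            seed=base_seed,
        )


def _build_members(cfg: DASDConfig) -> list[ClassifierContract]:
    out: list[ClassifierContract] = []
    for name in cfg.members:
        key = name.upper()
        if key == "SVM":
            out.append(SVMAdapter())
        elif key == "DLA":
            out.append(DLAAdapter(seed=cfg.seed))
        elif key == "LOGISTIC":
            out.append(LogisticAdapter())
        elif key == "EKNN":
            out.append(EKNNClassifier(
                k=cfg.eknn_k, cases_per_class=cfg.eknn_cases_per_class, seed=cfg.seed))
        else:
            raise ValueError(f"unknown ensemble member {name!r}")
    return out


def run_dasd(raw: Dataset, config: DASDConfig | None = None) -> dict:
    """Full pipeline: split -> BGWO -> BGA -> ensemble -> metrics.

    One stratified train/validation/test split is drawn up front; the two
    wrapper filters are driven by the train and validation parts, the
    feature mask is applied to all three parts and the row mask to the
    training part, and the ensemble is then trained, selected and tested
    on the filtered split.  Returns a JSON-serializable report containing
    the resolved seeds, the masks, per-member validation accuracies, the
    selected method, and the test-set metrics.
    """
    config = config or DASDConfig()
    train, val, test = stratified_split(raw, config.split)

    report: dict = {
        "seeds": {
            "split": config.split.seed,
            "bgwo": config.bgwo.seed if config.bgwo else None,
            "bga": config.bga.seed if config.bga else None,
            "pipeline": config.seed,
        },
        "n_samples": {"train": train.n_samples, "val": val.n_samples, "test": test.n_samples},
    }

    if config.bgwo is not None:
        try:
            fmask = run_bgwo(train, val, config.bgwo)
        except Exception as exc:
            raise RuntimeError(f"[feature-filter] {exc}") from exc
        train = train.select_features(fmask.keep)
        val = val.select_features(fmask.keep)
        test = test.select_features(fmask.keep)
        report["feature_filter"] = {
            "kept_features": fmask.kept_names,
            "fitness": fmask.fitness,
        }
    else:
        report["feature_filter"] = None

    if config.bga is not None:
        try:
            smask = run_bga(train, val, config.bga)
        except Exception as exc:
            raise RuntimeError(f"[outlier-filter] {exc}") from exc
        train = train.select_samples(smask.keep)
        report["outlier_filter"] = {
            "kept_samples": smask.kept_ids,
            "fitness": smask.fitness,
        }
    else:
        report["outlier_filter"] = None

    try:
        result = run_edm(train, val, test, _build_members(config))
    except Exception as exc:
        raise RuntimeError(f"[ensemble] {exc}") from exc

    report["validation_accuracy"] = result.accuracies
    report["best_method"] = result.best_method
    report["member_failures"] = result.failures
    report["test_scores"] = result.test_scores
    report["test_predictions"] = result.test_predictions.tolist()
    return report
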