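"""Binary Grey Wolf Optimization (BGWO) wrapper feature selection.

A pack of wolves with continuous positions searches the space of feature
subsets.  Each iteration, positions are binarized per dimension through a
sigmoid transfer function with Bernoulli thresholding, each candidate mask
is scored by the validation accuracy of the weighted-KNN base classifier
trained on the masked features (minus a small sparsity penalty), and the
three best-so-far wolves (alpha, beta, delta) steer the canonical
grey-wolf encircling update with the coefficient ``a`` decreasing linearly
from 2 to 0.  The global best mask is retained across iterations
(elitism), so best fitness is monotone in the iteration index.

Classification accuracy is a step function of the mask: on strongly
separable panels many subsets reach identical validation accuracy and the
subset is underdetermined.  The search objective therefore adds a small
continuous neighbourhood-margin term (mean squared-distance contrast
between each validation sample's nearest other-class and nearest
same-class training neighbours in the masked weight space), weighted well
below one validation sample's worth of accuracy, so that among
equal-accuracy masks the optimizer prefers subsets in which every kept
feature adds class evidence.  The reported :func:`mask_fitness` remains
the plain accuracy-minus-penalty score.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

from .core_io import Dataset
from .eknn import weighted_knn_accuracy
from .weighting import fit_weighting, to_weight_space

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BGWOConfig:
    population_size: int = 20
    max_iter: int = 100
    a_schedule: tuple[float, float] = (2.0, 0.0)  # linear decrease endpoints
    sparsity_penalty: float = 0.01
    margin_weight: float = 0.02  # weight of the continuous tie-refinement term
    k: int = 3  # neighbour count of the wrapper's base classifier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (three leaders + pack)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.sparsity_penalty < 0:
            raise ValueError("sparsity_penalty must be >= 0")


@dataclasses.dataclass
class FeatureMask:
    keep: np.ndarray  # bool per feature
    feature_names: list[str]
    fitness: float = float("nan")
    history: np.ndarray | None = None  # best fitness after init and each iteration

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.feature_names) != len(self.keep):
            raise ValueError("mask/feature_names length mismatch")
        if not self.keep.any():
            raise ValueError("an accepted feature mask must keep at least one feature")

    @property
    def kept_names(self) -> list[str]:
        return [n for n, k in zip(self.feature_names, self.keep) if k]


def mask_fitness(mask: np.ndarray, train: Dataset, val: Dataset,
                 penalty: float = 0.01, k: int = 3) -> float:
    """Wrapper fitness of one candidate mask.

    Validation accuracy of the base classifier on the masked feature space,
    minus ``penalty`` times the kept-feature fraction; the degenerate
    all-false mask scores 0.
    """
    mask = np.asarray(mask, dtype=bool)
    n_kept = int(mask.sum())
    if n_kept == 0:
        return 0.0
    acc = weighted_knn_accuracy(train.select_features(mask), val.select_features(mask), k=k)
    return acc - penalty * n_kept / len(mask)


def neighborhood_margin(train: Dataset, val: Dataset, k: int = 3) -> float:
    """Mean squared-distance contrast between other-class and same-class
    nearest training neighbours of each validation sample, in weight space.

    Additive over features in expectation: every feature with genuine class
    signal raises it, a pure-noise feature leaves it near zero.  Used only
    to refine the search among equal-accuracy masks.
    """
    weighting = fit_weighting(train)
    ref = to_weight_space(weighting, train.values)
    qry = to_weight_space(weighting, val.values)
    d2 = cdist(qry, ref, "sqeuclidean")
    same = train.labels[None, :] == val.labels[:, None]
    contrast = np.empty(val.n_samples)
    for i in range(val.n_samples):
        d_same = np.sort(d2[i][same[i]])[:k].mean()
        d_diff = np.sort(d2[i][~same[i]])[:k].mean()
        contrast[i] = d_diff - d_same
    return float(contrast.mean())


def run_bgwo(train: Dataset, val: Dataset, cfg: BGWOConfig | None = None) -> FeatureMask:
    """Search for the best feature subset; deterministic under ``cfg.seed``."""
    cfg = cfg or BGWOConfig()
    n_feat = train.n_features
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        """Search objective: reported fitness plus the margin refinement."""
        key = np.packbits(mask).tobytes()
        if key not in cache:
            f = mask_fitness(mask, train, val, cfg.sparsity_penalty, cfg.k)
            if mask.any() and cfg.margin_weight > 0:
                f += cfg.margin_weight * neighborhood_margin(
                    train.select_features(mask), val.select_features(mask), cfg.k)
            cache[key] = f
        return cache[key]

    pos = rng.uniform(-2.0, 2.0, size=(cfg.population_size, n_feat))
    # leaders: elitist (position, mask, fitness), alpha first
    leaders: list[tuple[np.ndarray, np.ndarray, float]] = []

    def binarize(p: np.ndarray) -> np.ndarray:
        return rng.uniform(size=n_feat) < expit(p)

    def offer(p: np.ndarray, mask: np.ndarray, f: float) -> None:
        for rank in range(3):
            if rank >= len(leaders) or f > leaders[rank][2]:
                leaders.insert(rank, (p.copy(), mask.copy(), f))
                del leaders[3:]
                return

    masks = [binarize(p) for p in pos]
    for p, m in zip(pos, masks):
        offer(p, m, fitness(m))
    history = [leaders[0][2]]

    a0, a1 = cfg.a_schedule
    for t in range(1, cfg.max_iter + 1):
        a = a0 + (a1 - a0) * t / cfg.max_iter
        leader_pos = np.stack([l[0] for l in leaders])
        for i in range(cfg.population_size):
            cand = np.empty((3, n_feat))
            for j in range(3):
                r1 = rng.uniform(size=n_feat)
                r2 = rng.uniform(size=n_feat)
                A = 2.0 * a * r1 - a
                C = 2.0 * r2
                D = np.abs(C * leader_pos[j] - pos[i])
                cand[j] = leader_pos[j] - A * D
            pos[i] = cand.mean(axis=0)
            m = binarize(pos[i])
            offer(pos[i], m, fitness(m))
        history.append(leaders[0][2])

    _, best_mask, best_fit = leaders[0]
    if not best_mask.any():  # only possible if every evaluated mask was empty
        best_mask = np.ones(n_feat, dtype=bool)
        best_fit = fitness(best_mask)
    return FeatureMask(
        keep=best_mask,
        feature_names=train.feature_names,
        fitness=best_fit,
        history=np.asarray(history),
    )
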