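"""Chimp Optimization Algorithm (COA) as prototype generation.

Instance reduction for the enhanced-KNN classifier: a population of
real-valued search agents ("chimps"), each encoding a small per-class set
of artificial training cases ("New-cases") in weight space, is evolved to
maximize the fraction of real training cases that a K-nearest-neighbour
vote over the encoded New-cases diagnoses correctly.  The winning agent
(the *attacker*) is decoded into the prototype set that replaces the full
training data at prediction time, so the final classifier is both small and
fast.

Encoding
--------
An agent is a flat vector of length ``Dim = A * N_C * Y_D`` laid out
class-major (positive class block first), then New-case, then feature:
``A`` weight-space coordinates per New-case, ``N_C`` New-cases per class,
``Y_D`` (= 2) classes.

Search dynamics
---------------
The four fittest agents — attacker, barrier, chaser and driver — steer the
rest of the population.  Each non-leader agent either moves to the mean of
four leader-relative candidate positions (driving/encircling), or, with 50%
probability, relocates chaotically via a quadratic map of its normalized
position (modelling the chimps' sexual-motivation phase).  The attack
coefficient ``fc`` decreases linearly from 2 to 0 over the run, and each
leader has its own pair of dynamic coefficients whose iteration schedules
differ by group.

All random draws are made outside the update equations and injected through
:class:`CoefficientBundle`, so every equation is unit-testable against
pinned values.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and encoding


@dataclasses.dataclass
class COAConfig:
    """Run parameters for the prototype-generation search.

    ``features_per_case`` (A) is the weight-space dimensionality of one
    New-case; ``cases_per_class`` (N_C) New-cases are generated for each of
    the ``n_classes`` (Y_D = 2) categories, so agents have dimension
    ``A * N_C * Y_D``.  ``k`` is the neighbour count of the fitness vote,
    ``u`` the quadratic-map constant, and ``bounds`` the per-dimension
    [lo, hi] box (defaults to the weighted training data's ranges).
    """

    features_per_case: int
    cases_per_class: int = 2
    n_classes: int = 2
    population_size: int = 20
    max_iter: int = 100
    k: int = 3
    u: float = 1.0
    bounds: np.ndarray | None = None  # shape (Dim, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (four leader roles)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if min(self.features_per_case, self.cases_per_class, self.n_classes) < 1:
            raise ValueError("encoding counts must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)
            if self.bounds.shape != (self.dim, 2):
                raise ValueError(f"bounds must have shape ({self.dim}, 2)")
            if not np.isfinite(self.bounds).all():
                raise ValueError("bounds must be finite")

    @property
    def dim(self) -> int:
        """Agent dimension Dim = A * N_C * Y_D."""
        return self.features_per_case * self.cases_per_class * self.n_classes


#: class labels of the encoding blocks, positive class first
BLOCK_CLASSES = (1, 0)


@dataclasses.dataclass
class PrototypeSet:
    """Per-class New-cases in weight space (the reduced training set)."""

    cases: np.ndarray  # (v, A) stacked class-major
    labels: np.ndarray  # (v,) in {0, 1}

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.cases.ndim != 2 or len(self.labels) != self.cases.shape[0]:
            raise ValueError("cases/labels shape mismatch")

    @property
    def v(self) -> int:
        """Total prototype count."""
        return self.cases.shape[0]


def decode(position: np.ndarray, cfg: COAConfig) -> PrototypeSet:
    """Flat agent position -> per-class New-cases (Table-layout order)."""
    position = np.asarray(position, dtype=float)
    if position.shape != (cfg.dim,):
        raise ValueError(f"position length {position.shape} != Dim {cfg.dim}")
    blocks = position.reshape(cfg.n_classes, cfg.cases_per_class, cfg.features_per_case)
    cases = blocks.reshape(-1, cfg.features_per_case)
    labels = np.repeat(BLOCK_CLASSES[: cfg.n_classes], cfg.cases_per_class)
    return PrototypeSet(cases=cases, labels=labels)


def encode(p: PrototypeSet) -> np.ndarray:
    """Inverse of :func:`decode` (prototypes must be in class-major order)."""
    return p.cases.reshape(-1).copy()


# ---------------------------------------------------------------------------
# fitness (fraction of training cases the prototype-KNN diagnoses correctly)


def knn_predict(ref: np.ndarray, ref_labels: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Majority vote over the k nearest references (Euclidean).

    Stable distance ordering; an even-vote tie falls back to the nearest
    reference's label.
    """
    d = cdist(np.atleast_2d(query), np.atleast_2d(ref))
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    votes = ref_labels[order]
    pos = votes.sum(axis=1)
    pred = np.where(2 * pos > k, 1, np.where(2 * pos < k, 0, votes[:, 0]))
    return pred.astype(int)


def eval_agent(position: np.ndarray, train_w: np.ndarray, train_labels: np.ndarray,
               cfg: COAConfig) -> float:
    """Fitness of one agent: fraction of training cases correctly diagnosed
    by a K-NN vote over its decoded New-cases, in [0, 1]."""
    proto = decode(position, cfg)
    k = cfg.k
    if k > proto.v:
        logger.warning("k=%d exceeds prototype count v=%d; clipping", k, proto.v)
        k = proto.v
    pred = knn_predict(proto.cases, proto.labels, train_w, k)
    return float((pred == np.asarray(train_labels)).mean())


# ---------------------------------------------------------------------------
# coefficient schedules


def compute_fc(itr: int, max_itr: int) -> float:
    """Attack coefficient, linearly decreasing from 2 (itr=0) to 0 (itr=max)."""
    if not 0 <= itr <= max_itr:
        raise ValueError(f"itr={itr} outside [0, {max_itr}]")
    return 2.0 - 2.0 * (itr / max_itr)


def compute_dynamic_coeffs(itr: int, max_itr: int, draws) -> np.ndarray:
    """Leader-group random factors rc, shape (4, 2).

    ``draws`` are eight uniforms in [0, 1]; each is scaled by its group's
    dynamic coefficient.  The groups deliberately use heterogeneous
    iteration exponents (quartic/cube roots and cubic ramps), so early-run
    factors can exceed 1.
    """
    if max_itr <= 0:
        raise ValueError("max_itr must be positive")
    draws = np.asarray(draws, dtype=float).reshape(4, 2)
    if ((draws < 0) | (draws > 1)).any():
        raise ValueError("draws must lie in [0, 1]")
    t, m = float(itr), float(max_itr)
    cube = (t ** 3) / (m ** 3)
    k = np.array(
        [
            [1.95 - 2.0 * t ** 0.25 / m ** (1.0 / 3.0), 2.0 * t ** (1.0 / 3.0) / m ** (1.0 / 3.0) + 0.5],
            [1.95 - 2.0 * t ** (1.0 / 3.0) / m ** 0.25, 2.0 * cube + 0.5],
            [-3.0 * cube + 1.5, 2.0 * t ** (1.0 / 3.0) / m ** (1.0 / 3.0) + 0.5],
            [-2.0 * cube + 0.5, 2.0 * cube + 0.5],
        ]
    )
    return k * draws


def compute_ac_cc(fc: float, rc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-leader coefficient vectors: Ac_k = |2*fc*rc_k1 - fc|, Cc_k = 2*rc_k2."""
    rc = np.asarray(rc, dtype=float).reshape(4, 2)
    ac = np.abs(2.0 * fc * rc[:, 0] - fc)
    cc = 2.0 * rc[:, 1]
    return ac, cc


def compute_mc(position: np.ndarray, bounds: np.ndarray, u: float = 1.0) -> np.ndarray:
    """Chaotic (quadratic-map) vector in [0, 1] per dimension.

    The position is normalized to s = (x - lo) / (hi - lo) and mapped to
    ``|s^2 - u|``; degenerate dimensions (hi == lo) yield 0.
    """
    position = np.asarray(position, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    s = np.where(span > 0, (position - lo) / np.where(span > 0, span, 1.0), 0.0)
    mc = np.abs(s ** 2 - u)
    return np.where(span > 0, mc, 0.0)


# ---------------------------------------------------------------------------
# position updates


@dataclasses.dataclass
class CoefficientBundle:
    """All per-update random quantities, injected for testability."""

    fc: float
    rc: np.ndarray  # (4, 2)
    ac: np.ndarray  # (4,)
    cc: np.ndarray  # (4,)
    mc: np.ndarray  # (Dim,)
    z: float

    @classmethod
    def draw(cls, itr: int, max_itr: int, position: np.ndarray, bounds: np.ndarray,
             u: float, rng: np.random.Generator) -> "CoefficientBundle":
        fc = compute_fc(itr, max_itr)
        rc = compute_dynamic_coeffs(itr, max_itr, rng.uniform(size=8))
        ac, cc = compute_ac_cc(fc, rc)
        mc = compute_mc(position, bounds, u)
        return cls(fc=fc, rc=rc, ac=ac, cc=cc, mc=mc, z=float(rng.uniform()))


def leader_candidates(position: np.ndarray, leader_positions: np.ndarray,
                      coeffs: CoefficientBundle) -> np.ndarray:
    """Four leader-relative candidate positions, shape (4, Dim), unclipped.

    candidate_k = leader_k - Ac_k * |Cc_k * leader_k - mc * position|,
    with the chaotic vector ``mc`` applied element-wise.
    """
    leader_positions = np.asarray(leader_positions, dtype=float)
    dc = np.abs(coeffs.cc[:, None] * leader_positions - coeffs.mc[None, :] * position[None, :])
    return leader_positions - coeffs.ac[:, None] * dc


def position_update(position: np.ndarray, leader_positions: np.ndarray,
                    coeffs: CoefficientBundle, bounds: np.ndarray) -> np.ndarray:
    """One agent move: mean of the four candidates if z < 0.5, otherwise a
    chaotic relocation x_d = lo_d + mc_d * (hi_d - lo_d); clipped to bounds."""
    if coeffs.z < 0.5:
        new = leader_candidates(position, leader_positions, coeffs).mean(axis=0)
    else:
        new = bounds[:, 0] + coeffs.mc * (bounds[:, 1] - bounds[:, 0])
    return np.clip(new, bounds[:, 0], bounds[:, 1])


# ---------------------------------------------------------------------------
# main loop


@dataclasses.dataclass
class COAResult:
    prototypes: PrototypeSet
    attacker_position: np.ndarray
    attacker_fitness: float
    fitness_history: np.ndarray  # attacker fitness after init and each iteration


def _default_bounds(train_w: np.ndarray, cfg: COAConfig) -> np.ndarray:
    """Tile per-weight-coordinate [min, max] of the training data to Dim."""
    lo = train_w.min(axis=0)
    hi = train_w.max(axis=0)
    per_case = np.stack([lo, hi], axis=1)  # (A, 2)
    return np.tile(per_case, (cfg.cases_per_class * cfg.n_classes, 1))


def coa_optimize(train_w: np.ndarray, train_labels: np.ndarray, cfg: COAConfig) -> COAResult:
    """Run the full search and return the attacker plus its history.

    The population is initialized uniformly inside the bounds; the four
    leaders are elitist (replaced only by a strictly fitter agent, ties
    resolved by agent order), so attacker fitness is monotone
    non-decreasing.  Only non-leader positions are updated each iteration.
    """
    train_w = np.asarray(train_w, dtype=float)
    train_labels = np.asarray(train_labels, dtype=int)
    if train_w.ndim != 2 or train_w.shape[0] == 0:
        raise ValueError("weighted training data must be a non-empty 2-D array")
    q = train_w.shape[0]
    if train_w.shape[1] != cfg.features_per_case:
        raise ValueError(
            f"features_per_case={cfg.features_per_case} does not match "
            f"weighted data width {train_w.shape[1]}"
        )
    v = cfg.cases_per_class * cfg.n_classes
    if v >= q:
        raise ValueError(f"prototype count v={v} must be smaller than Q={q}")

    bounds = cfg.bounds if cfg.bounds is not None else _default_bounds(train_w, cfg)
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(cfg.seed)

    pop = lo + rng.uniform(size=(cfg.population_size, cfg.dim)) * (hi - lo)
    fit = np.array([eval_agent(p, train_w, train_labels, cfg) for p in pop])

    # elitist leader snapshots: (position, fitness), best first
    order = np.argsort(-fit, kind="stable")[:4]
    leaders = [(pop[i].copy(), float(fit[i])) for i in order]
    history = [leaders[0][1]]

    def offer(position: np.ndarray, f: float) -> None:
        """Insert into the leader hierarchy if strictly fitter."""
        for rank in range(4):
            if f > leaders[rank][1]:
                leaders.insert(rank, (position.copy(), float(f)))
                leaders.pop()
                return

    for itr in range(1, cfg.max_iter + 1):
        leader_pos = np.stack([l[0] for l in leaders])
        # leaders live as elitist snapshots outside the population, so every
        # population member is a non-leader and moves each iteration
        for i in range(cfg.population_size):
            coeffs = CoefficientBundle.draw(itr, cfg.max_iter, pop[i], bounds, cfg.u, rng)
            pop[i] = position_update(pop[i], leader_pos, coeffs, bounds)
            fit[i] = eval_agent(pop[i], train_w, train_labels, cfg)
            offer(pop[i], fit[i])
        history.append(leaders[0][1])

    attacker_pos, attacker_fit = leaders[0]
    return COAResult(
        prototypes=decode(attacker_pos, cfg),
        attacker_position=attacker_pos,
        attacker_fitness=attacker_fit,
        fitness_history=np.asarray(history),
    )


def run_coa(train_w: np.ndarray, train_labels: np.ndarray, cfg: COAConfig) -> PrototypeSet:
    """Convenience wrapper returning only the decoded attacker prototypes."""
    return coa_optimize(train_w, train_labels, cfg).prototypes
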