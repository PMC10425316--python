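import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dasd import (
    COAConfig,
    CoefficientBundle,
    PrototypeSet,
    coa_optimize,
    compute_ac_cc,
    compute_dynamic_coeffs,
    compute_fc,
    compute_mc,
    decode,
    encode,
    eval_agent,
    leader_candidates,
    position_update,
    run_coa,
)


def _cfg(**kw):
    base = dict(features_per_case=2, cases_per_class=1, population_size=4, max_iter=5)
    base.update(kw)
    return COAConfig(**base)


class TestEncoding:
    @pytest.mark.parametrize("a,nc,yd,dim", [(4, 2, 2, 16), (1, 1, 2, 2), (3, 5, 2, 30)])
    def test_agent_dimension(self, a, nc, yd, dim):
        cfg = COAConfig(features_per_case=a, cases_per_class=nc, n_classes=yd)
        assert cfg.dim == dim

    def test_decode_layout_is_class_major(self):
        cfg = _cfg(features_per_case=2, cases_per_class=2)
        pos = np.arange(8, dtype=float)
        p = decode(pos, cfg)
        # positive-class block first, then negative class; case-major within
        np.testing.assert_array_equal(p.cases, [[0, 1], [2, 3], [4, 5], [6, 7]])
        assert p.labels.tolist() == [1, 1, 0, 0]

    def test_roundtrip(self):
        cfg = _cfg(features_per_case=3, cases_per_class=2)
        rng = np.random.default_rng(0)
        pos = rng.uniform(size=cfg.dim)
        assert np.array_equal(encode(decode(pos, cfg)), pos)

    def test_wrong_length(self):
        with pytest.raises(ValueError, match="Dim"):
            decode(np.zeros(5), _cfg())


class TestEvalAgent:
    def test_prototypes_on_training_cases_score_one(self):
        cfg = _cfg(features_per_case=2, cases_per_class=2, k=1)
        train = np.array([[0.1, 0.1], [0.2, 0.2], [0.8, 0.8], [0.9, 0.9]])
        labels = np.array([1, 1, 0, 0])
        pos = encode(PrototypeSet(cases=train, labels=labels))
        assert eval_agent(pos, train, labels, cfg) == 1.0

    def test_three_of_four_correct(self):
        cfg = _cfg(features_per_case=2, cases_per_class=1, k=1)
        pos = np.array([0.0, 0.0, 1.0, 1.0])  # one prototype per class
        train = np.array([[0.1, 0.1], [0.9, 0.9], [0.2, 0.2], [0.3, 0.3]])
        labels = np.array([1, 0, 1, 0])  # last case sits on the wrong side
        assert eval_agent(pos, train, labels, cfg) == 0.75

    def test_k_clipped_with_warning(self, caplog):
        cfg = _cfg(features_per_case=1, cases_per_class=1, k=5)
        train = np.array([[0.1], [0.9], [0.2]])
        labels = np.array([1, 0, 1])
        pos = np.array([0.0, 1.0])
        with caplog.at_level("WARNING"):
            eval_agent(pos, train, labels, cfg)
        assert "clipping" in caplog.text

    def test_matches_bruteforce_oracle(self):
        """Vectorized fitness equals an explicit loop-and-sort oracle."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = rng.integers(1, 4)
            nc = rng.integers(1, 4)
            k = rng.integers(1, 4)
            q = rng.integers(3, 12)
            cfg = COAConfig(features_per_case=int(a), cases_per_class=int(nc),
                            population_size=4, k=int(k))
            train = rng.uniform(size=(q, a))
            labels = rng.integers(0, 2, size=q)
            pos = rng.uniform(size=cfg.dim)
            proto = decode(pos, cfg)
            kk = min(k, proto.v)
            correct = 0
            for h in range(q):
                dists = [math.dist(train[h], proto.cases[j]) for j in range(proto.v)]
                order = sorted(range(proto.v), key=lambda j: (dists[j], j))[:kk]
                votes = [int(proto.labels[j]) for j in order]
                pos_votes = sum(votes)
                if 2 * pos_votes > kk:
                    pred = 1
                elif 2 * pos_votes < kk:
                    pred = 0
                else:
                    pred = votes[0]
                correct += pred == labels[h]
            assert eval_agent(pos, train, labels, cfg) == pytest.approx(correct / q)


class TestCoefficients:
    def test_fc_endpoints_and_midpoint(self):
        assert compute_fc(0, 100) == 2.0
        assert compute_fc(100, 100) == 0.0
        assert compute_fc(50, 100) == 1.0

    def test_fc_out_of_range(self):
        with pytest.raises(ValueError):
            compute_fc(101, 100)
        with pytest.raises(ValueError):
            compute_fc(-1, 100)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 1000), st.integers(0, 1000))
    def test_fc_reflection_identity(self, max_itr, itr):
        itr = min(itr, max_itr)
        assert compute_fc(itr, max_itr) + compute_fc(max_itr - itr, max_itr) == pytest.approx(2.0)

    def test_dynamic_coefficients_at_final_iteration(self):
        """Closed forms where the iteration ratio cancels."""
        rc = compute_dynamic_coeffs(100, 100, np.ones(8))
        assert rc[1, 1] == pytest.approx(2.5)  # second-group cubic ramp + 0.5
        assert rc[2, 0] == pytest.approx(-1.5)  # third-group: -3 + 1.5
        assert rc[0, 0] == pytest.approx(1.95 - 2 * 100 ** 0.25 / 100 ** (1 / 3))
        assert rc[0, 0] == pytest.approx(0.58742, abs=1e-5)

    def test_dynamic_coefficients_scale_draws(self):
        draws = np.full(8, 0.5)
        rc = compute_dynamic_coeffs(100, 100, draws)
        np.testing.assert_allclose(rc, compute_dynamic_coeffs(100, 100, np.ones(8)) * 0.5)

    def test_dynamic_coefficients_validation(self):
        with pytest.raises(ValueError):
            compute_dynamic_coeffs(1, 0, np.zeros(8))
        with pytest.raises(ValueError):
            compute_dynamic_coeffs(1, 10, np.full(8, 1.5))

    def test_ac_cc_pinned_values(self):
        ac, cc = compute_ac_cc(2.0, np.column_stack([np.full(4, 0.5), np.full(4, 0.5)]))
        np.testing.assert_allclose(ac, 0.0, atol=1e-12)  # |2*2*0.5 - 2| = 0
        np.testing.assert_allclose(cc, 1.0)
        ac, _ = compute_ac_cc(1.0, np.column_stack([np.ones(4), np.zeros(4)]))
        np.testing.assert_allclose(ac, 1.0)


class TestChaoticMap:
    def test_extremes(self):
        bounds = np.array([[0.0, 1.0]])
        assert compute_mc(np.array([1.0]), bounds) == pytest.approx(0.0)
        assert compute_mc(np.array([0.0]), bounds) == pytest.approx(1.0)

    def test_degenerate_bounds(self):
        bounds = np.array([[0.5, 0.5]])
        assert compute_mc(np.array([0.5]), bounds) == pytest.approx(0.0)

    def test_range_sweep(self):
        rng = np.random.default_rng(1)
        bounds = np.column_stack([np.full(10, -2.0), np.full(10, 3.0)])
        for _ in range(1000):
            x = rng.uniform(-2, 3, size=10)
            mc = compute_mc(x, bounds)
            assert ((mc >= 0) & (mc <= 1)).all()


def _bundle(dim, ac, cc, mc, z, fc=1.0):
    return CoefficientBundle(
        fc=fc, rc=np.zeros((4, 2)),
        ac=np.asarray(ac, float), cc=np.asarray(cc, float),
        mc=np.asarray(mc, float), z=z)


class TestPositionUpdate:
    def test_zero_attack_returns_leaders(self):
        leaders = np.arange(12, dtype=float).reshape(4, 3)
        b = _bundle(3, ac=np.zeros(4), cc=np.ones(4), mc=np.zeros(3), z=0.0)
        cand = leader_candidates(np.zeros(3), leaders, b)
        np.testing.assert_array_equal(cand, leaders)

    def test_mean_of_identical_leaders(self):
        p = np.array([0.3, 0.7])
        leaders = np.tile(p, (4, 1))
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
        b = _bundle(2, ac=np.zeros(4), cc=np.ones(4), mc=np.zeros(2), z=0.3)
        np.testing.assert_allclose(position_update(np.zeros(2), leaders, b, bounds), p)

    def test_candidates_match_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = rng.integers(1, 6)
            x = rng.uniform(size=d)
            leaders = rng.uniform(size=(4, d))
            b = _bundle(d, ac=rng.uniform(0, 2, 4), cc=rng.uniform(0, 2, 4),
                        mc=rng.uniform(size=d), z=0.0)
            cand = leader_candidates(x, leaders, b)
            for k in range(4):
                for j in range(d):
                    dc = abs(b.cc[k] * leaders[k, j] - b.mc[j] * x[j])
                    assert cand[k, j] == pytest.approx(leaders[k, j] - b.ac[k] * dc)

    def test_chaotic_branch_relocates_to_lower_bound(self):
        bounds = np.array([[0.0, 1.0]])
        x = np.array([1.0])  # upper bound -> s=1 -> mc=0 -> relocate to lo
        b = _bundle(1, ac=np.zeros(4), cc=np.ones(4),
                    mc=compute_mc(x, bounds), z=0.9)
        out = position_update(x, np.tile(x, (4, 1)), b, bounds)
        assert out[0] == pytest.approx(0.0)

    def test_chaotic_branch_frequency(self):
        """The 50% gate between encircling and chaotic relocation."""
        rng = np.random.default_rng(11)
        bounds = np.array([[0.0, 1.0]])
        leaders = np.full((4, 1), 0.5)
        chaotic = 0
        n = 100_000
        for _ in range(n):
            x = np.array([0.25])  # mc = |0.0625 - 1| = 0.9375 -> relocation lands at mc
            b = CoefficientBundle.draw(1, 2, x, bounds, 1.0, rng)
            b.ac = np.zeros(4)  # encircling branch then returns the leader mean 0.5
            out = position_update(x, leaders, b, bounds)
            chaotic += out[0] == pytest.approx(0.9375)
        assert chaotic / n == pytest.approx(0.5, abs=0.01)


class TestRunCOA:
    @staticmethod
    def _clouds(seed=0, q=40):
        rng = np.random.default_rng(seed)
        half = q // 2
        w = np.vstack([
            rng.uniform(0.0, 0.3, size=(half, 2)),
            rng.uniform(0.7, 1.0, size=(half, 2)),
        ])
        y = np.repeat([1, 0], half)
        return w, y

    def test_attacker_reaches_high_fitness_on_separable_clouds(self):
        w, y = self._clouds()
        cfg = COAConfig(features_per_case=2, cases_per_class=2,
                        population_size=20, max_iter=100, seed=0)
        res = coa_optimize(w, y, cfg)
        assert res.attacker_fitness >= 0.95

    def test_attacker_fitness_monotone(self):
        w, y = self._clouds(seed=1)
        cfg = COAConfig(features_per_case=2, cases_per_class=2,
                        population_size=8, max_iter=50, seed=3)
        res = coa_optimize(w, y, cfg)
        assert (np.diff(res.fitness_history) >= 0).all()
        assert len(res.fitness_history) == cfg.max_iter + 1

    def test_prototypes_within_bounds(self):
        w, y = self._clouds(seed=2)
        cfg = COAConfig(features_per_case=2, cases_per_class=3,
                        population_size=8, max_iter=30, seed=5)
        proto = run_coa(w, y, cfg)
        assert (proto.cases >= w.min(axis=0) - 1e-12).all()
        assert (proto.cases <= w.max(axis=0) + 1e-12).all()

    def test_prototype_set_must_shrink_data(self):
        w, y = self._clouds(q=6)
        cfg = COAConfig(features_per_case=2, cases_per_class=3, population_size=4)
        with pytest.raises(ValueError, match="smaller than Q"):
            run_coa(w, y, cfg)

    def test_deterministic_under_seed(self):
        w, y = self._clouds(seed=3)
        cfg = COAConfig(features_per_case=2, cases_per_class=2,
                        population_size=8, max_iter=20, seed=9)
        a = run_coa(w, y, cfg)
        b = run_coa(w, y, cfg)
        np.testing.assert_array_equal(a.cases, b.cases)

    def test_single_prototype_recovery_smoke(self):
        """K=1 with one New-case per class classifies held-out cloud points."""
        w, y = self._clouds(seed=4, q=40)
        cfg = COAConfig(features_per_case=2, cases_per_class=1,
                        population_size=16, max_iter=60, k=1, seed=2)
        proto = run_coa(w[:-2], y[:-2], cfg)
        from dasd import knn_predict
        held = w[-2:]
        np.testing.assert_array_equal(knn_predict(proto.cases, proto.labels, held, 1), y[-2:])

    def test_population_too_small(self):
        with pytest.raises(ValueError, match="population_size"):
            COAConfig(features_per_case=2, population_size=3)
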