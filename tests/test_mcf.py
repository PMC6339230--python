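"""Mapping-comparison functions against independent brute-force oracles."""

import numpy as np
import pytest

from pftcal import (
    TrainingSet,
    mcf_dir,
    mcf_dist,
    mcf_distc,
    mcf_from_spec,
    mcf_fused,
    mcf_reg,
)

from conftest import random_instance


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive: explicit loops, textbook formulas)
# ---------------------------------------------------------------------------

def oracle_reg(E, T):
    """Normal-equations linear fit per axis, then ((R2x * R2y))**2."""
    X = np.column_stack([np.ones(len(E)), E])
    r2 = []
    for axis in range(2):
        y = T[:, axis]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        pred = X @ beta
        ss_res = np.sum((pred - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2.append(1 - ss_res / ss_tot)
    return (r2[0] * r2[1]) ** 2


def oracle_dist(E, T):
    M = len(E)
    count = 0
    for i in range(M - 2):
        for j in range(i + 1, M - 1):
            for k in range(j + 1, M):
                de = np.linalg.norm(E[i] - E[k])
                dt = np.linalg.norm(T[i] - T[k])
                if de == 0 or dt == 0:
                    continue
                a = np.linalg.norm(E[i] - E[j]) / de - 1
                b = np.linalg.norm(T[i] - T[j]) / dt - 1
                if b == 0:
                    continue
                if a / b > 0:
                    count += 1
    return float(count)


def oracle_distc(E, T):
    de = [np.linalg.norm(E[i + 1] - E[i]) for i in range(len(E) - 1)]
    dt = [np.linalg.norm(T[i + 1] - T[i]) for i in range(len(T) - 1)]
    de, dt = np.array(de), np.array(dt)
    if de.std() == 0 or dt.std() == 0:
        return 0.0
    return float(np.corrcoef(de, dt)[0, 1])


def oracle_dir(E, T, flip=False):
    M = len(E)
    total = 0.0
    for i in range(M - 1):
        for j in range(i + 1, M):
            if flip:
                ve = np.array([E[i, 0] - E[j, 0], E[j, 1] - E[i, 1]])
            else:
                ve = E[j] - E[i]
            vt = T[j] - T[i]
            ne, nt = np.linalg.norm(ve), np.linalg.norm(vt)
            if ne == 0 or nt == 0:
                continue
            total += ve @ vt / (ne * nt)
    return total


def _ts_of(E, T_sets):
    return TrainingSet(E, T_sets)


def _single_target_ts(E, T):
    """Training set where each fixation has exactly the mapped target."""
    return TrainingSet(E, [t[None, :] for t in T]), np.zeros(len(E), dtype=int)


class TestRegression:
    def test_exact_linear_relation_scores_one(self):
        # single eye attribute, targets exactly linear in it
        e = np.array([0.0, 1.0, 2.0, 3.0])
        E = e[:, None]
        T = np.column_stack([10 + 5 * e, 20 - 3 * e])
        ts, m = _single_target_ts(E, T)
        assert mcf_reg(ts, m) == pytest.approx(1.0)

    def test_constant_features_score_zero_with_warning(self):
        E = np.tile([5.0, 7.0], (6, 1))
        T = np.random.default_rng(0).uniform(0, 100, (6, 2))
        ts, m = _single_target_ts(E, T)
        with pytest.warns(UserWarning, match="degenerate"):
            assert mcf_reg(ts, m) == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            E = rng.uniform(0, 400, (8, 2))
            T = rng.uniform(0, 100, (8, 2))
            ts, m = _single_target_ts(E, T)
            assert mcf_reg(ts, m) == pytest.approx(oracle_reg(E, T), abs=1e-10)

    def test_constant_targets_with_zero_residuals_score_one(self):
        E = np.random.default_rng(1).uniform(0, 400, (6, 2))
        T = np.tile([40.0, 60.0], (6, 1))
        ts, m = _single_target_ts(E, T)
        assert mcf_reg(ts, m) == pytest.approx(1.0)


class TestDistanceRatio:
    def test_similarity_transform_makes_all_triples_positive(self):
        T = np.array([[0.0, 0], [1, 0], [3, 0], [7, 0]])
        E = 2 * T + np.array([100.0, 50.0])
        ts, m = _single_target_ts(E, T)
        assert mcf_dist(ts, m) == 4.0  # C(4,3)

    def test_opposite_orderings_give_zero(self):
        # E-ratio 3 (farther) vs T-ratio 0.2 (closer): P < 0
        E = np.array([[0.0, 0], [30, 0], [10, 0]])
        T = np.array([[0.0, 0], [2, 0], [10, 0]])
        ts, m = _single_target_ts(E, T)
        assert mcf_dist(ts, m) == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            E = rng.uniform(0, 400, (6, 2))
            T = rng.uniform(0, 100, (6, 2))
            ts, m = _single_target_ts(E, T)
            assert mcf_dist(ts, m) == oracle_dist(E, T)

    def test_degenerate_denominators_contribute_zero(self):
        E = np.array([[0.0, 0], [1, 0], [0, 0]])  # ||E1,E3|| = 0
        T = np.array([[0.0, 0], [1, 0], [2, 0]])
        ts, m = _single_target_ts(E, T)
        assert mcf_dist(ts, m) == 0.0


class TestDistanceCorrelation:
    def test_proportional_series_score_one(self):
        # neighbor distances (1, 2, 3) vs (2, 4, 6)
        E = np.array([[0.0, 0], [1, 0], [3, 0], [6, 0]])
        T = np.array([[0.0, 0], [2, 0], [6, 0], [12, 0]])
        ts, m = _single_target_ts(E, T)
        assert mcf_distc(ts, m) == pytest.approx(1.0)

    def test_constant_series_convention_zero(self):
        E = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])  # distances all 1
        T = np.random.default_rng(2).uniform(0, 100, (4, 2))
        ts, m = _single_target_ts(E, T)
        assert mcf_distc(ts, m) == 0.0

    def test_matches_pearson_oracle(self, rng):
        for _ in range(5):
            E = rng.uniform(0, 400, (10, 2))
            T = rng.uniform(0, 100, (10, 2))
            ts, m = _single_target_ts(E, T)
            assert mcf_distc(ts, m) == pytest.approx(
                oracle_distc(E, T), abs=1e-10
            )


class TestDirection:
    def test_flip_makes_mirrored_pair_parallel(self):
        E = np.array([[10.0, 10.0], [20.0, 20.0]])
        T = np.array([[50.0, 50.0], [40.0, 60.0]])
        ts, m = _single_target_ts(E, T)
        assert mcf_dir(ts, m, flip_horizontal=True) == pytest.approx(1.0)
        assert mcf_dir(ts, m, flip_horizontal=False) == pytest.approx(0.0)

    def test_matches_pair_loop_oracle(self, rng):
        for flip in (False, True):
            E = rng.uniform(0, 400, (7, 2))
            T = rng.uniform(0, 100, (7, 2))
            ts, m = _single_target_ts(E, T)
            assert mcf_dir(ts, m, flip_horizontal=flip) == pytest.approx(
                oracle_dir(E, T, flip=flip), abs=1e-10
            )

    def test_requires_2d_features(self):
        ts = TrainingSet(np.zeros((3, 3)), [np.zeros((1, 2))] * 3)
        with pytest.raises(ValueError, match="2-D"):
            mcf_dir(ts, np.zeros(3, dtype=int))

    def test_translation_and_scale_invariance(self, rng):
        E = rng.uniform(0, 400, (6, 2))
        T = rng.uniform(0, 100, (6, 2))
        ts, m = _single_target_ts(E, T)
        base = mcf_dir(ts, m)
        ts2, _ = _single_target_ts(3.7 * E + 55.0, T)
        assert mcf_dir(ts2, m) == pytest.approx(base, abs=1e-9)
        ts3 = TrainingSet(E, [(0.2 * t + 11.0)[None, :] for t in T])
        assert mcf_dir(ts3, m) == pytest.approx(base, abs=1e-9)


class TestPermutationInvariance:
    """reg and dir sum over unordered pairs, so a joint permutation of
    fixations and their chosen targets leaves them unchanged.  distc depends
    on the fixation ORDER (consecutive distances), and dist anchors each
    triple's distance ratios at its lowest index, so neither is invariant in
    general."""

    def test_joint_permutation(self, rng):
        E = rng.uniform(0, 400, (7, 2))
        T = rng.uniform(0, 100, (7, 2))
        perm = rng.permutation(7)
        for fn, invariant in [
            (mcf_reg, True),
            (mcf_dir, True),
            (mcf_distc, False),
            (mcf_dist, False),
        ]:
            ts, m = _single_target_ts(E, T)
            tsp, mp = _single_target_ts(E[perm], T[perm])
            a, b = fn(ts, m), fn(tsp, mp)
            if invariant:
                assert a == pytest.approx(b, abs=1e-9), fn.__name__
            else:
                assert a != pytest.approx(b, abs=1e-9), fn.__name__


class TestFusion:
    def test_identity_fusion_equals_component(self, rng):
        ts = random_instance(rng, 6)
        m = np.zeros(6, dtype=int)
        fused = mcf_fused(ts, m, [("distc", 1.0)])
        assert fused == pytest.approx(mcf_distc(ts, m))

    def test_zero_weight_component_ignored(self, rng):
        ts = random_instance(rng, 6)
        m = np.zeros(6, dtype=int)
        fused = mcf_fused(ts, m, [("dir", 0.0), ("distc", 1.0)],
                          normalize=False)
        assert fused == pytest.approx(mcf_distc(ts, m))

    def test_dir_plus_distc_normalized(self, rng):
        # the best-performing fusion family: dir + 0.3 * distc
        ts = random_instance(rng, 8)
        m = np.zeros(8, dtype=int)
        got = mcf_fused(ts, m, [("dir", 1.0), ("distc", 0.3)], normalize=True)
        pairs = 8 * 7 / 2
        expected = mcf_dir(ts, m) / pairs + 0.3 * mcf_distc(ts, m)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown MCF"):
            mcf_from_spec("bogus")


def test_all_scores_finite_on_degenerate_geometry():
    """Coincident features/targets hit every zero-branch; scores stay finite."""
    E = np.zeros((5, 2))
    E[2] = [1.0, 1.0]
    T = np.zeros((5, 2))
    ts = TrainingSet(E, [T[i][None, :] for i in range(5)])
    m = np.zeros(5, dtype=int)
    with pytest.warns(UserWarning):
        scores = [mcf_reg(ts, m), mcf_dist(ts, m), mcf_distc(ts, m),
                  mcf_dir(ts, m)]
    assert np.all(np.isfinite(scores))
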