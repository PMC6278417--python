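"""TOPSIS normalization, ideal points, distances, and ranking invariants."""

import numpy as np
import pytest

import poserank as pr
from poserank.topsis import ideal_points, minkowski_distance, normalize

WEIGHTS = (0.633, 0.228, 0.044, 0.095)


def random_dm(rng, m=5, n=3):
    dirs = [rng.choice(["benefit", "cost"]) for _ in range(n)]
    criteria = tuple(pr.CriterionSpec(f"c{j}", dirs[j]) for j in range(n))
    values = rng.uniform(-10, 10, size=(m, n))
    return pr.DecisionMatrix(tuple(f"a{i}" for i in range(m)),
                             criteria, values)


def dominates(values, dirs, i, k):
    """Row i at least as good as row k on every directed criterion."""
    for j, d in enumerate(dirs):
        a, b = values[i, j], values[k, j]
        if d == "benefit" and a < b:
            return False
        if d == "cost" and a > b:
            return False
    return True


class TestNormalize:
    def test_three_four_five(self):
        r = normalize(np.array([[3.0], [4.0]]))
        np.testing.assert_allclose(r[:, 0], [0.6, 0.8])

    def test_sign_preserved(self):
        r = normalize(np.array([[-3.0], [-4.0]]))
        np.testing.assert_allclose(r[:, 0], [-0.6, -0.8])

    def test_columns_have_unit_norm(self, rng):
        x = rng.uniform(-50, 50, size=(8, 4))
        r = normalize(x)
        np.testing.assert_allclose(np.linalg.norm(r, axis=0), 1.0,
                                   atol=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.uniform(-50, 50, size=(6, 3))
        for c in (0.01, 3.0, 1e4):
            np.testing.assert_allclose(normalize(x * c), normalize(x),
                                       atol=1e-12)

    def test_zero_column_warns_and_stays_zero(self):
        with pytest.warns(UserWarning):
            r = normalize(np.array([[0.0, 1.0], [0.0, 2.0]]))
        assert (r[:, 0] == 0).all()

    def test_minmax_maps_to_unit_interval(self, rng):
        r = normalize(rng.uniform(-5, 5, size=(7, 3)), method="minmax")
        assert r.min() >= 0 and r.max() <= 1


class TestIdealPoints:
    def test_single_alternative(self):
        v = np.array([[1.0, 2.0]])
        ap, am = ideal_points(v, ["benefit", "cost"])
        np.testing.assert_array_equal(ap, v[0])
        np.testing.assert_array_equal(am, v[0])

    def test_cost_column_ideal_is_most_negative(self, isatin_poses):
        # weighted energy column of the reference matrix: ideal = min
        dm = pr.build_decision_matrix(isatin_poses)
        v = normalize(dm) * np.asarray(WEIGHTS)
        ap, am = ideal_points(v, dm.directions)
        assert ap[1] == pytest.approx(v[:, 1].min())
        assert am[1] == pytest.approx(v[:, 1].max())

    def test_constant_column_collapses(self):
        v = np.array([[2.0], [2.0], [2.0]])
        ap, am = ideal_points(v, ["cost"])
        assert ap[0] == am[0] == 2.0

    def test_direction_count_checked(self):
        with pytest.raises(pr.ConfigError):
            ideal_points(np.ones((2, 3)), ["cost"])


class TestMinkowskiDistance:
    def test_euclidean_three_four_five(self):
        assert minkowski_distance([0, 0], [3, 4], 2) == pytest.approx(5.0)

    def test_manhattan(self):
        assert minkowski_distance([1, 1], [0, 0], 1) == pytest.approx(2.0)

    def test_matches_numpy_norm(self, rng):
        for _ in range(30):
            a, b = rng.normal(size=(2, 6))
            assert minkowski_distance(a, b, 2) == pytest.approx(
                float(np.linalg.norm(a - b)), abs=1e-12)

    def test_exponent_below_one_rejected(self):
        with pytest.raises(pr.DataDomainError):
            minkowski_distance([0], [1], 0.5)


class TestRank:
    def test_reference_matrix_top_pose(self, obidoxime_poses):
        dm = pr.build_decision_matrix(obidoxime_poses)
        res = pr.rank(dm, weights=WEIGHTS, s=2.0)
        assert res.best == "Dock8"

    def test_identical_rows_tie_stably(self):
        criteria = (pr.CriterionSpec("c0", "cost"),
                    pr.CriterionSpec("c1", "benefit"))
        dm = pr.DecisionMatrix(("a", "b", "c"), criteria,
                               [[1.0, 2.0], [1.0, 2.0], [5.0, 1.0]])
        res = pr.rank(dm, weights=(0.5, 0.5))
        assert res.closeness[0] == res.closeness[1]
        assert res.ranking[:2] == (0, 1)        # input order preserved
        assert res.ranks[0] == res.ranks[1] == 1  # shared rank
        assert res.ranks[2] == 3

    def test_degenerate_all_identical_gives_half(self):
        criteria = (pr.CriterionSpec("c0", "cost"),)
        dm = pr.DecisionMatrix(("a", "b"), criteria, [[2.0], [2.0]])
        with pytest.warns(UserWarning):
            res = pr.rank(dm, weights=(1.0,))
        np.testing.assert_array_equal(res.closeness, [0.5, 0.5])

    def test_closeness_bounds_and_extremes(self, rng):
        for _ in range(25):
            dm = random_dm(rng, m=6, n=3)
            res = pr.rank(dm, weights=(0.5, 0.3, 0.2))
            assert (res.closeness >= 0).all()
            assert (res.closeness <= 1).all()
            for i in range(6):
                if np.allclose(res.weighted[i], res.ideal):
                    assert res.closeness[i] == pytest.approx(1.0)
                if np.allclose(res.weighted[i], res.anti_ideal) and \
                        not np.allclose(res.ideal, res.anti_ideal):
                    assert res.closeness[i] == pytest.approx(0.0)

    @pytest.mark.parametrize("s", [1.0, 2.0, 3.5])
    def test_weak_dominance_preserved(self, rng, s):
        for _ in range(60):
            dm = random_dm(rng)
            res = pr.rank(dm, weights=(0.5, 0.3, 0.2), s=s)
            for i in range(5):
                for k in range(5):
                    if i != k and dominates(dm.values, dm.directions, i, k):
                        assert res.closeness[i] >= res.closeness[k] - 1e-12

    def test_column_scale_invariance(self, rng):
        dm = random_dm(rng)
        res = pr.rank(dm, weights=(0.5, 0.3, 0.2))
        scaled = pr.DecisionMatrix(dm.alternatives, dm.criteria,
                                   dm.values * np.array([2.0, 0.1, 37.0]))
        res2 = pr.rank(scaled, weights=(0.5, 0.3, 0.2))
        assert res.ranking == res2.ranking
        np.testing.assert_allclose(res.closeness, res2.closeness, atol=1e-9)

    def test_row_permutation_equivariance(self, rng):
        dm = random_dm(rng, m=7)
        perm = rng.permutation(7)
        dm2 = pr.DecisionMatrix(
            tuple(dm.alternatives[i] for i in perm), dm.criteria,
            dm.values[perm])
        r1 = pr.rank(dm, weights=(0.5, 0.3, 0.2))
        r2 = pr.rank(dm2, weights=(0.5, 0.3, 0.2))
        np.testing.assert_allclose(r2.closeness, r1.closeness[perm],
                                   atol=1e-12)

    def test_weight_validation(self, obidoxime_poses):
        dm = pr.build_decision_matrix(obidoxime_poses)
        with pytest.raises(pr.ConfigError):
            pr.rank(dm, weights=(0.5, 0.5))          # wrong length
        with pytest.raises(pr.ConfigError):
            pr.rank(dm, weights=(0.7, 0.2, 0.2, 0.2))  # sum != 1
        with pytest.raises(pr.ConfigError):
            pr.rank(dm)                               # no weights anywhere

    def test_weights_taken_from_criteria(self, obidoxime_poses):
        criteria = tuple(
            pr.CriterionSpec(c.name, c.direction, w)
            for c, w in zip(pr.DEFAULT_CRITERIA, WEIGHTS))
        dm = pr.build_decision_matrix(obidoxime_poses, criteria)
        assert pr.rank(dm).best == "Dock8"
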