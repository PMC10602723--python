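"""Judgment matrices, priority weights, and consistency testing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from indexweaver import (
    JudgmentMatrix,
    aggregate_expert_matrices,
    build_judgment_matrix,
    consistency_ratio,
    priority_weights,
)
from indexweaver.ahp import (
    MatrixError,
    RANDOM_INDEX,
    read_matrix_csv,
    write_matrix_csv,
)
from indexweaver.simulate import simulate_judgment_matrix

from _oracles import principal_eigen_3x3


def consistent_matrix(w):
    w = np.asarray(w, dtype=float)
    ids = tuple(f"W{k}" for k in range(w.size))
    return JudgmentMatrix(ids=ids, values=np.outer(w, 1.0 / w))


def random_reciprocal(rng, n):
    """Random Saaty-grade reciprocal matrix."""
    grades = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            g = rng.choice(grades)
            entry = g if rng.random() < 0.5 else 1.0 / g
            a[i, j], a[j, i] = entry, 1.0 / entry
    return JudgmentMatrix(ids=tuple(f"x{k}" for k in range(n)), values=a)


class TestMatrixInvariants:
    def test_rejects_non_reciprocal(self):
        with pytest.raises(MatrixError, match="reciprocal"):
            JudgmentMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_rejects_non_positive(self):
        with pytest.raises(MatrixError, match="positive"):
            JudgmentMatrix(("a", "b"), np.array([[1.0, -2.0], [-0.5, 1.0]]))

    def test_rejects_out_of_scale(self):
        with pytest.raises(MatrixError, match="Saaty"):
            JudgmentMatrix(("a", "b"), np.array([[1.0, 12.0], [1 / 12.0, 1.0]]))

    def test_rejects_bad_diagonal(self):
        with pytest.raises(MatrixError, match="diagonal"):
            JudgmentMatrix(("a", "b"), np.array([[2.0, 1.0], [1.0, 1.0]]))


class TestBuildFromMeans:
    def test_equal_means_uniform(self):
        m = build_judgment_matrix({"a": 4.0, "b": 4.0, "c": 4.0})
        assert np.allclose(m.values, 1.0)
        assert np.allclose(priority_weights(m).weights, 1 / 3)

    def test_half_point_gap_is_grade_two(self):
        m = build_judgment_matrix({"a": 4.6, "b": 4.1}, step=0.5)
        assert m.values[0, 1] == 2.0
        w = priority_weights(m).weights
        assert np.allclose(w, [2 / 3, 1 / 3], atol=1e-10)

    def test_full_point_gap_is_grade_three(self):
        m = build_judgment_matrix({"a": 4.8, "b": 3.8}, step=0.5)
        assert m.values[0, 1] == 3.0
        assert np.allclose(priority_weights(m).weights, [0.75, 0.25], atol=1e-10)

    def test_sign_gives_reciprocal_entry(self):
        m = build_judgment_matrix({"a": 3.8, "b": 4.8}, step=0.5)
        assert m.values[0, 1] == pytest.approx(1 / 3)

    def test_grade_caps_at_nine(self):
        m = build_judgment_matrix({"a": 5.0, "b": 1.0}, step=0.1)
        assert m.values[0, 1] == 9.0

    def test_too_few_siblings(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_judgment_matrix({"a": 4.0})


class TestPriorityWeights:
    def test_two_by_two_closed_form(self):
        m = JudgmentMatrix(("B7", "B8"), np.array([[1.0, 2.0], [0.5, 1.0]]))
        res = priority_weights(m)
        assert np.allclose(res.weights, [2 / 3, 1 / 3], atol=1e-12)
        assert res.lambda_max == pytest.approx(2.0, abs=1e-10)
        assert res.cr == 0.0 and res.consistent

    def test_consistent_matrix_recovers_weights(self):
        w = np.array([0.5, 0.3, 0.2])
        res = priority_weights(consistent_matrix(w))
        assert np.allclose(res.weights, w, atol=1e-10)
        assert res.lambda_max == pytest.approx(3.0, abs=1e-10)

    def test_matches_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = random_reciprocal(rng, 3)
            res = priority_weights(m)
            w_ref, lam_ref = principal_eigen_3x3(m.values)
            assert np.allclose(res.weights, w_ref, atol=1e-8)
            assert res.lambda_max == pytest.approx(lam_ref, abs=1e-8)

    def test_geometric_mean_agrees_on_consistent(self):
        w = np.array([0.4, 0.35, 0.15, 0.1])
        m = consistent_matrix(w)
        eig = priority_weights(m, "eigenvector").weights
        gm = priority_weights(m, "geometric_mean").weights
        assert np.allclose(eig, gm, atol=1e-10)

    def test_methods_close_when_nearly_consistent(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(60):
            w = rng.dirichlet(np.ones(4)) + 0.05
            m = simulate_judgment_matrix(w / w.sum(), 0.08, rng)
            res = priority_weights(m, "eigenvector")
            if res.cr >= 0.1:
                continue
            gm = priority_weights(m, "geometric_mean")
            assert np.max(np.abs(res.weights - gm.weights)) < 0.02
            checked += 1
        assert checked >= 20

    def test_scale_free(self):
        w = np.array([3.0, 2.0, 1.0])
        a = priority_weights(consistent_matrix(w)).weights
        b = priority_weights(consistent_matrix(10 * w)).weights
        assert np.allclose(a, b, atol=1e-12)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="method"):
            priority_weights(consistent_matrix([0.5, 0.5]), "simplex")


class TestConsistency:
    def test_order_two_always_consistent(self):
        m = JudgmentMatrix(("a", "b"), np.array([[1.0, 7.0], [1 / 7.0, 1.0]]))
        ci, ri, cr, ok = consistency_ratio(m)
        assert (ci, cr, ok) == (0.0, 0.0, True)

    @pytest.mark.parametrize("n", [3, 5, 8, 15])
    def test_consistent_any_order(self, n):
        rng = np.random.default_rng(n)
        w = rng.dirichlet(np.ones(n)) + 0.1
        # keep ratios within the Saaty scale
        w = w / w.sum()
        vals = np.outer(w, 1.0 / w)
        if vals.max() > 9:
            pytest.skip("ratios fell outside the Saaty scale")
        ci, ri, cr, ok = consistency_ratio(
            JudgmentMatrix(tuple(f"x{k}" for k in range(n)), vals))
        assert ci == pytest.approx(0.0, abs=1e-9)
        assert cr == pytest.approx(0.0, abs=1e-9)
        assert ok

    def test_three_by_three_against_oracle(self):
        m = JudgmentMatrix(
            ("a", "b", "c"),
            np.array([[1, 2, 6], [0.5, 1, 2], [1 / 6, 0.5, 1]]),
        )
        _, lam_ref = principal_eigen_3x3(m.values)
        ci, ri, cr, ok = consistency_ratio(m)
        assert ci == pytest.approx((lam_ref - 3) / 2, abs=1e-8)
        assert cr == pytest.approx((lam_ref - 3) / 2 / 0.58, abs=1e-8)
        assert ok is (cr < 0.1)

    def test_order_beyond_table_errors(self):
        n = len(RANDOM_INDEX) + 1
        ids = tuple(f"x{k}" for k in range(n))
        with pytest.raises(ValueError, match=str(len(RANDOM_INDEX))):
            consistency_ratio(JudgmentMatrix(ids, np.ones((n, n))))

    def test_lambda_max_at_least_n_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for n in (3, 4, 5, 6):
            for _ in range(10):
                res = priority_weights(random_reciprocal(rng, n))
                assert res.lambda_max >= n - 1e-9


class TestAggregation:
    def test_single_matrix_identity(self):
        m = random_reciprocal(np.random.default_rng(1), 4)
        agg = aggregate_expert_matrices([m])
        assert np.allclose(agg.values, m.values, atol=1e-12)

    def test_reciprocity_closure(self):
        rng = np.random.default_rng(2)
        ms = [random_reciprocal(rng, 5) for _ in range(7)]
        agg = aggregate_expert_matrices(ms)
        assert np.allclose(agg.values * agg.values.T, 1.0, atol=1e-12)

    def test_aggregate_converges_to_consistent(self):
        """Geometric-mean aggregation of many noisy expert matrices around
        the same latent weights approaches the consistent matrix."""
        rng = np.random.default_rng(3)
        w = np.array([0.4, 0.3, 0.2, 0.1])
        ms = [simulate_judgment_matrix(w, 0.1, rng) for _ in range(200)]
        agg = aggregate_expert_matrices(ms)
        assert np.max(np.abs(agg.values - consistent_matrix(w).values)) < 0.1
        assert np.allclose(priority_weights(agg).weights, w, atol=0.01)

    def test_shape_mismatch(self):
        rng = np.random.default_rng(4)
        with pytest.raises(MatrixError, match="identical ids"):
            aggregate_expert_matrices(
                [random_reciprocal(rng, 3), random_reciprocal(rng, 4)])


@given(st.integers(0, 2**31 - 1), st.integers(2, 6))
def test_reciprocity_preserved_by_constructors(seed, n):
    rng = np.random.default_rng(seed)
    means = {f"i{k}": float(rng.uniform(1, 5)) for k in range(n)}
    m = build_judgment_matrix(means)
    assert np.allclose(m.values * m.values.T, 1.0, atol=1e-12)


class TestMatrixCsv:
    def test_round_trip(self, tmp_path):
        m = random_reciprocal(np.random.default_rng(9), 4)
        path = tmp_path / "m.csv"
        write_matrix_csv(m, path)
        back = read_matrix_csv(path)
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values, atol=0, rtol=0)

    def test_fraction_entries(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",a,b\na,1,1/3\nb,3,1\n")
        m = read_matrix_csv(path)
        assert m.values[0, 1] == pytest.approx(1 / 3)

    def test_bad_entry_reports_line(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",a,b\na,1,zebra\nb,3,1\n")
        with pytest.raises(MatrixError, match="line 2"):
            read_matrix_csv(path)
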