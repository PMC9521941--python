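import numpy as np
import pytest

from tdfe import (
    ExpressionMatrix,
    ExpressionTensor,
    SyntheticSpec,
    factor_product_vector,
    fold,
    hosvd,
    make_infection_tensor,
    svd,
    tensor_label,
    unfold,
)
from tdfe.workflows import tensor_component_indices


def matrix_of(values):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(values, tuple(f"g{i}" for i in range(n)), tuple(f"s{j}" for j in range(m)))


class TestSVD:
    def test_rank_one(self):
        u = np.array([3.0, 4.0]) / 5.0
        v = np.array([1.0, 0.0, 0.0])
        res = svd(matrix_of(3.0 * np.outer(u, v)))
        assert res.singular_values[0] == pytest.approx(3.0)
        np.testing.assert_allclose(np.abs(res.feature_vectors[:, 0]), np.abs(u), atol=1e-12)
        np.testing.assert_allclose(np.abs(res.sample_vectors[:, 0]), np.abs(v), atol=1e-12)

    def test_diagonal(self):
        res = svd(matrix_of(np.diag([3.0, 2.0])))
        np.testing.assert_allclose(res.singular_values, [3.0, 2.0])

    def test_gram_matrix_oracle(self, rng):
        """Feature vectors are eigenvectors of X X^T (independent eigh)."""
        x = rng.standard_normal((5, 4))
        res = svd(matrix_of(x))
        evals, evecs = np.linalg.eigh(x @ x.T)
        order = np.argsort(evals)[::-1]
        for l in range(4):
            dot = abs(evecs[:, order[l]] @ res.feature_vectors[:, l])
            assert dot == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(np.sort(evals)[::-1][:4], res.singular_values**2, rtol=1e-10)

    def test_sample_vectors_proportional_to_xtu(self, random_matrix):
        res = svd(random_matrix)
        for l in range(1, res.singular_values.size + 1):
            lhs = random_matrix.values.T @ res.component(l, axis="feature")
            np.testing.assert_allclose(
                lhs, res.singular_values[l - 1] * res.component(l, axis="sample"), atol=1e-10
            )

    def test_reconstruction_and_orthonormality(self, random_matrix):
        res = svd(random_matrix)
        rel = np.linalg.norm(res.reconstruct() - random_matrix.values) / np.linalg.norm(
            random_matrix.values
        )
        assert rel < 1e-8
        for f in (res.feature_vectors, res.sample_vectors):
            np.testing.assert_allclose(f.T @ f, np.eye(f.shape[1]), atol=1e-8)

    def test_sign_convention_deterministic(self, random_matrix):
        res = svd(random_matrix)
        again = svd(random_matrix)
        np.testing.assert_array_equal(res.feature_vectors, again.feature_vectors)
        # largest-|component| entry of each u is positive
        idx = np.abs(res.feature_vectors).argmax(axis=0)
        assert (res.feature_vectors[idx, np.arange(idx.size)] > 0).all()

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            matrix_of([[np.inf, 1.0], [0.0, 1.0]])


class TestUnfoldFold:
    def test_two_mode_identity(self):
        t = ExpressionTensor(np.arange(6.0).reshape(2, 3), ("gene", "sample"), gene_mode="gene")
        np.testing.assert_array_equal(unfold(t, "gene").values, t.values)

    def test_2x2x2_layout(self):
        t = ExpressionTensor(
            np.arange(1.0, 9.0).reshape(2, 2, 2), ("a", "b", "c"), gene_mode="a"
        )
        # rows: mode a; columns: (b, c) with c (last-listed) varying fastest
        np.testing.assert_array_equal(
            unfold(t, "a").values, [[1, 2, 3, 4], [5, 6, 7, 8]]
        )
        # unfolding on b: columns (a, c), c fastest
        np.testing.assert_array_equal(
            unfold(t, "b").values, [[1, 2, 5, 6], [3, 4, 7, 8]]
        )

    def test_round_trip(self, rng):
        t = ExpressionTensor(rng.standard_normal((3, 4, 5)), ("x", "y", "z"), gene_mode="x")
        for mode in t.mode_names:
            back = fold(unfold(t, mode), mode, t)
            np.testing.assert_array_equal(back.values, t.values)

    def test_unknown_mode(self, random_tensor):
        with pytest.raises(KeyError):
            unfold(random_tensor, "nope")


class TestHOSVD:
    def test_outer_product(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        c = np.array([3.0, 4.0]) / 5.0
        t = ExpressionTensor(
            2.0 * np.einsum("i,j,k->ijk", a, b, c), ("a", "b", "c"), gene_mode="a"
        )
        res = hosvd(t)
        core = res.core
        flat = np.abs(core).reshape(-1)
        assert np.max(flat) == pytest.approx(2.0)
        assert np.sum(flat > 1e-10) == 1
        for mode, vec in (("a", a), ("b", b), ("c", c)):
            assert abs(res.factor_column(mode, 1) @ vec) == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        t = ExpressionTensor(rng.standard_normal((4, 3, 2)), ("a", "b", "c"), gene_mode="a")
        res = hosvd(t)
        rel = np.linalg.norm(res.reconstruct() - t.values) / np.linalg.norm(t.values)
        assert rel < 1e-8

    def test_gene_factors_match_unfolding_svd(self, random_tensor):
        """Gene-mode factor columns equal left singular vectors of the
        gene-mode unfolding (the identity the method rests on)."""
        res = hosvd(random_tensor)
        direct = svd(unfold(random_tensor, "gene"))
        k = direct.singular_values.size
        for l in range(k):
            dot = abs(direct.feature_vectors[:, l] @ res.factors["gene"][:, l])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_core_all_orthogonal(self, random_tensor):
        res = hosvd(random_tensor)
        core = res.core
        for axis in range(core.ndim):
            moved = np.moveaxis(core, axis, 0).reshape(core.shape[axis], -1)
            gram = moved @ moved.T
            off = gram - np.diag(np.diag(gram))
            assert np.abs(off).max() < 1e-8 * max(1.0, np.abs(gram).max())

    def test_factor_orthonormality(self, random_tensor):
        res = hosvd(random_tensor)
        for f in res.factors.values():
            assert np.abs(f.T @ f - np.eye(f.shape[1])).max() < 1e-8

    def test_truncation_flag(self, random_tensor):
        res = hosvd(random_tensor, rank={"gene": 2})
        assert res.factors["gene"].shape == (6, 2)
        assert res.core.shape[0] == 2

    def test_rejects_one_mode(self):
        with pytest.raises(ValueError):
            ExpressionTensor(np.zeros(3), ("a",), gene_mode="a")


class TestFactorProductVector:
    def test_constant_factors(self):
        t = ExpressionTensor(np.ones((3, 2, 2)) + np.eye(2)[None], ("g", "b", "c"), gene_mode="g")
        res = hosvd(t)
        # leading factors of each sample-structure mode are near-constant here
        vec = factor_product_vector(res, {"b": 1, "c": 1})
        assert vec.shape == (4,)
        assert np.ptp(np.abs(vec)) < 0.2 * np.abs(vec).max()

    def test_missing_mode_raises(self, random_tensor):
        res = hosvd(random_tensor)
        with pytest.raises(KeyError):
            factor_product_vector(res, {"cell_line": 1})

    def test_matches_design_on_planted_tensor(self):
        """At strong planted effect the chosen factor outer product tracks
        the treatment-contrast design over sample-structure cells."""
        spec = SyntheticSpec(n_features=400, n_deg=10, effect=8.0, seed=11)
        tensor, _ = make_infection_tensor(spec)
        res = hosvd(tensor)
        indices = tensor_component_indices(res, "treatment")
        vec = factor_product_vector(res, indices)
        y = tensor_label(*spec.mode_sizes).values
        r = np.corrcoef(vec, y)[0, 1]
        assert abs(r) > 0.9
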