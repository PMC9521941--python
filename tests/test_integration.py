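import numpy as np
import pytest

from oracles import collapse_triple_loop
from tdfe import (
    ExpressionMatrix,
    PairedOmics,
    SyntheticSpec,
    collapse,
    integrated_svd,
    make_paired_omics,
    match_factors,
    recover_sample_vectors,
    svd,
)


def pair_of(mrna, mirna):
    mrna = np.asarray(mrna, dtype=float)
    mirna = np.asarray(mirna, dtype=float)
    sample_ids = tuple(f"s{j}" for j in range(mrna.shape[1]))
    return PairedOmics(
        ExpressionMatrix(mrna, tuple(f"m{i}" for i in range(mrna.shape[0])), sample_ids),
        ExpressionMatrix(mirna, tuple(f"r{k}" for k in range(mirna.shape[0])), sample_ids),
    )


class TestCollapse:
    def test_single_sample_outer_product(self):
        pair = pair_of([[2.0], [3.0]], [[5.0], [-1.0]])
        np.testing.assert_allclose(
            collapse(pair, standardize_first=False).values, [[10, -2], [15, -3]]
        )

    def test_hand_product(self):
        pair = pair_of([[1.0, 2.0], [0.0, 1.0]], [[1.0, 0.0]])
        np.testing.assert_allclose(collapse(pair, standardize_first=False).values, [[1], [0]])

    def test_triple_loop_oracle(self, rng):
        mrna = rng.standard_normal((8, 5))
        mirna = rng.standard_normal((6, 5))
        out = collapse(pair_of(mrna, mirna), standardize_first=False)
        np.testing.assert_allclose(out.values, collapse_triple_loop(mrna, mirna), rtol=1e-12)

    def test_equals_matrix_product_identity(self, rng):
        mrna = rng.standard_normal((7, 4))
        mirna = rng.standard_normal((5, 4))
        out = collapse(pair_of(mrna, mirna), standardize_first=False)
        np.testing.assert_allclose(out.values, mrna @ mirna.T, rtol=1e-14)

    def test_axis_ids(self, rng):
        pair = pair_of(rng.standard_normal((3, 4)), rng.standard_normal((2, 4)))
        out = collapse(pair, standardize_first=False)
        assert out.feature_ids == pair.mrna.feature_ids
        assert out.sample_ids == pair.mirna.feature_ids


class TestIntegratedSVD:
    def test_shared_sample_vectors_recover_both_factor_sets(self):
        """When the two matrices share sample-mode singular vectors, the SVD
        of the collapse reproduces both feature factor sets with singular
        values lambda_l * lambda'_l."""
        pair, truth = make_paired_omics(
            SyntheticSpec(n_features=60, n_mirna=40, class_sizes=(5, 5), seed=5),
            shared_rank=3,
            noise=0.0,
        )
        res = integrated_svd(pair, standardize_first=False)
        expected_sv = truth.mrna_singular_values * truth.mirna_singular_values
        np.testing.assert_allclose(res.singular_values[:3], expected_sv, rtol=1e-8)
        _, cos_m = match_factors(truth.mrna_factors, res.feature_vectors[:, :3])
        _, cos_r = match_factors(truth.mirna_factors, res.sample_vectors[:, :3])
        assert cos_m.min() > 0.999
        assert cos_r.min() > 0.999

    def test_rank_one_pair_single_dominant_value(self, rng):
        u = rng.standard_normal((10, 1))
        up = rng.standard_normal((8, 1))
        v = rng.standard_normal((6, 1))
        pair = pair_of(u @ v.T, up @ v.T)
        res = integrated_svd(pair, standardize_first=False)
        assert res.singular_values[0] > 0
        np.testing.assert_allclose(res.singular_values[1:], 0.0, atol=1e-10)

    def test_orthogonal_sample_vectors_collapse_to_zero(self):
        v1 = np.array([1.0, 0.0, 0.0])
        v2 = np.array([0.0, 1.0, 0.0])
        pair = pair_of(np.outer([1.0, 2.0], v1), np.outer([3.0, -1.0], v2))
        np.testing.assert_allclose(
            collapse(pair, standardize_first=False).values, 0.0, atol=1e-12
        )


class TestRecoverSampleVectors:
    def test_rank_one_recovers_lambda_v(self, rng):
        u = rng.standard_normal(10)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(5)
        v /= np.linalg.norm(v)
        lam = 6.0
        pair = pair_of(lam * np.outer(u, v), lam * np.outer(u[:4], v))
        res = integrated_svd(pair, standardize_first=False)
        u_m, _ = recover_sample_vectors(pair, res, 1, standardize_first=False)
        # recovered vector is lambda * v up to the factor's sign
        ratio = u_m / v
        np.testing.assert_allclose(np.abs(ratio), lam, rtol=1e-8)

    def test_shared_v_high_correlation_with_noise(self):
        pair, _ = make_paired_omics(
            SyntheticSpec(n_features=200, n_mirna=80, class_sizes=(10, 10), seed=8),
            shared_rank=2,
            noise=0.05,
        )
        res = integrated_svd(pair, standardize_first=False)
        u_m, u_r = recover_sample_vectors(pair, res, 1, standardize_first=False)
        assert abs(np.corrcoef(u_m, u_r)[0, 1]) > 0.99

    def test_zero_matrix_gives_zero_vector(self, rng):
        base = pair_of(rng.standard_normal((4, 3)), rng.standard_normal((3, 3)))
        res = integrated_svd(base, standardize_first=False)
        zero_pair = pair_of(np.zeros((4, 3)), np.zeros((3, 3)))
        u_m, u_r = recover_sample_vectors(zero_pair, res, 1, standardize_first=False)
        np.testing.assert_array_equal(u_m, 0.0)
        np.testing.assert_array_equal(u_r, 0.0)
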