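"""Integrated mRNA x miRNA analysis through the sample-collapsed product matrix.

Two omics matrices measured on the same samples, ``x_ij`` (N mRNAs) and
``x_kj`` (K miRNAs), define a product tensor ``x_ijk = x_ij x_kj`` that is far
too large to materialize for genome-scale N and K.  Summing it over samples,

    x_ik = sum_j x_ij x_kj  =  X_mrna @ X_mirna^T,

gives an N x K matrix whose SVD approximates the gene-mode and miRNA-mode
factors of the full tensor decomposition.  When the two matrices share their
sample-mode singular vectors (v_l = v'_l), the SVD of the collapse recovers
*exactly* the feature factors of the separate per-matrix SVDs, with singular
values lambda_l * lambda'_l.  The missing sample-mode vectors are recovered by
back-projection, ``u_lj = sum_i x_ij u_li``.

This module never forms the N x M x K tensor: the collapse is a single matrix
product.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, PairedOmics, standardize
from .decomposition import SVDResult, svd

__all__ = [
    "collapse",
    "integrated_svd",
    "recover_sample_vectors",
    "match_factors",
]


def _maybe_standardize(pair: PairedOmics, do_standardize: bool) -> PairedOmics:
    if not do_standardize:
        return pair
    return PairedOmics(
        mrna=pair.mrna if pair.mrna.standardized else standardize(pair.mrna),
        mirna=pair.mirna if pair.mirna.standardized else standardize(pair.mirna),
    )


def collapse(pair: PairedOmics, standardize_first: bool = True) -> ExpressionMatrix:
    """Sample-summed product matrix ``x_ik = sum_j x_ij x_kj``.

    Computed as ``X_mrna @ X_mirna^T``; the three-mode product tensor is never
    materialized.  Both matrices are standardized first by default, matching
    the pipeline that consumes the factors.
    """
    pair = _maybe_standardize(pair, standardize_first)
    return ExpressionMatrix(
        values=pair.mrna.values @ pair.mirna.values.T,
        feature_ids=pair.mrna.feature_ids,
        sample_ids=pair.mirna.feature_ids,
    )


def integrated_svd(pair: PairedOmics, standardize_first: bool = True) -> SVDResult:
    """SVD of the collapsed matrix.

    ``feature_vectors`` approximates the mRNA-mode factors ``u_li`` and
    ``sample_vectors`` the miRNA-mode factors ``u_lk`` of the product-tensor
    decomposition.
    """
    return svd(collapse(pair, standardize_first=standardize_first))


def recover_sample_vectors(
    pair: PairedOmics,
    result: SVDResult,
    l: int,
    standardize_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project factor l (1-based) onto samples through each matrix.

    Returns ``(u_mrna, u_mirna)`` with ``u_mrna[j] = sum_i x_ij u_li`` and
    ``u_mirna[j] = sum_k x_kj u_lk``.  For matrices sharing sample-mode
    singular vectors the two are proportional to the same v_l, so they are
    highly correlated; the correlation is the practical check that a factor
    pair really reflects shared sample structure.
    """
    pair = _maybe_standardize(pair, standardize_first)
    u_i = result.component(l, axis="feature")
    u_k = result.component(l, axis="sample")
    if u_i.shape[0] != pair.mrna.n_features or u_k.shape[0] != pair.mirna.n_features:
        raise ValueError("factor lengths do not match the paired matrices")
    return pair.mrna.values.T @ u_i, pair.mirna.values.T @ u_k


def match_factors(reference: np.ndarray, candidate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy pairing of factor columns by absolute cosine similarity.

    Returns ``(pairing, cosines)`` where ``pairing[r]`` is the candidate
    column matched to reference column r and ``cosines[r]`` the absolute
    cosine similarity of that pair.  Each candidate column is used once.
    """
    ref = np.asarray(reference, float)
    cand = np.asarray(candidate, float)
    rn = ref / np.linalg.norm(ref, axis=0, keepdims=True)
    cn = cand / np.linalg.norm(cand, axis=0, keepdims=True)
    sim = np.abs(rn.T @ cn)
    pairing = np.full(ref.shape[1], -1)
    cosines = np.zeros(ref.shape[1])
    available = sim.copy()
    for _ in range(min(ref.shape[1], cand.shape[1])):
        r, c = np.unravel_index(np.argmax(available), available.shape)
        pairing[r] = c
        cosines[r] = sim[r, c]
        available[r, :] = -1.0
        available[:, c] = -1.0
    return pairing, cosines
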