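"""SVD/PCA and higher-order SVD (HOSVD) with the gram-matrix identities.

The central objects are the singular vectors of an expression matrix and the
per-mode factor matrices of an expression tensor.  In the unsupervised
feature-extraction convention, the left singular vectors ``u_l`` (one
component per gene) are the PC *scores* used for feature selection, and the
right singular vectors ``v_l`` (one component per sample) identify the sample
structure of interest.  They are related by the gram-matrix eigenproblems

    X X^T u_l = lambda_l^2 u_l,      X^T X v_l = lambda_l^2 v_l,

with ``v_l`` proportional to ``X^T u_l``; note the gram-matrix eigenvalue is
the *squared* singular value.

HOSVD computes, for each mode, the left singular vectors of that mode's
unfolding, then contracts the tensor with every factor's transpose to obtain
an all-orthogonal core.  At full rank the reconstruction is exact.

Component indices (``l``) are 1-based everywhere in this package, matching
the conventional numbering of principal components.

Sign convention: every factor column is flipped, if needed, so that its
largest-magnitude entry is positive; the flip is propagated to the paired
factor (SVD) or the core (HOSVD) so the reconstruction is unchanged.  This
makes decompositions deterministic functions of their input.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np

from .containers import ExpressionMatrix, ExpressionTensor

__all__ = [
    "SVDResult",
    "HOSVDResult",
    "svd",
    "hosvd",
    "unfold",
    "fold",
    "factor_product_vector",
]


def _sign_fix_columns(u: np.ndarray) -> np.ndarray:
    """Return +/-1 per column so the largest-|entry| of each column is positive."""
    idx = np.abs(u).argmax(axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return signs


@dataclass(frozen=True)
class SVDResult:
    """Thin SVD ``X = sum_l lambda_l u_l v_l^T`` with labeled factor axes.

    ``feature_vectors`` has shape (N, L) with column l-1 holding ``u_l``;
    ``sample_vectors`` has shape (M, L) holding ``v_l``.  Row labels are the
    feature/sample ids of the decomposed matrix.
    """

    singular_values: np.ndarray
    feature_vectors: np.ndarray
    sample_vectors: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def component(self, l: int, axis: str = "feature") -> np.ndarray:
        """Return u_l (axis='feature') or v_l (axis='sample'); l is 1-based."""
        if not 1 <= l <= self.singular_values.size:
            raise IndexError(f"component {l} out of range 1..{self.singular_values.size}")
        vecs = self.feature_vectors if axis == "feature" else self.sample_vectors
        return vecs[:, l - 1]

    def reconstruct(self) -> np.ndarray:
        return (self.feature_vectors * self.singular_values) @ self.sample_vectors.T


def svd(matrix: ExpressionMatrix) -> SVDResult:
    """Thin SVD of an expression matrix with the deterministic sign convention."""
    u, s, vt = np.linalg.svd(matrix.values, full_matrices=False)
    signs = _sign_fix_columns(u)
    return SVDResult(
        singular_values=s,
        feature_vectors=u * signs,
        sample_vectors=vt.T * signs,
        feature_ids=matrix.feature_ids,
        sample_ids=matrix.sample_ids,
    )


def _unfold_array(values: np.ndarray, axis: int) -> np.ndarray:
    # Rows: chosen mode. Columns: remaining modes in original order, the
    # last-listed mode varying fastest (C order after moving the axis first).
    return np.moveaxis(values, axis, 0).reshape(values.shape[axis], -1)


def unfold(tensor: ExpressionTensor, mode: str) -> ExpressionMatrix:
    """Matricize a tensor with `mode` as rows.

    Columns enumerate every index combination of the remaining modes, kept in
    their original order with the last-listed mode varying fastest.  Column
    ids are the underscore-joined labels of the contributing cells, so the
    operation is invertible (see :func:`fold`).
    """
    axis = tensor.axis(mode)
    mat = _unfold_array(tensor.values, axis)
    rest = [m for m in tensor.mode_names if m != mode]
    col_ids = [
        "_".join(combo)
        for combo in product(*(tensor.labels_for(m) for m in rest))
    ]
    return ExpressionMatrix(mat, tensor.labels_for(mode), tuple(col_ids))


def fold(
    matrix: ExpressionMatrix | np.ndarray,
    mode: str,
    template: ExpressionTensor,
) -> ExpressionTensor:
    """Inverse of :func:`unfold` with respect to `template`'s modes and labels."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    axis = template.axis(mode)
    rest_shape = [s for i, s in enumerate(template.values.shape) if i != axis]
    restored = np.moveaxis(values.reshape([values.shape[0]] + rest_shape), 0, axis)
    return ExpressionTensor(
        restored, template.mode_names, template.gene_mode, template.mode_labels
    )


@dataclass(frozen=True)
class HOSVDResult:
    """Full HOSVD: per-mode orthonormal factors and an all-orthogonal core.

    ``factors[mode]`` is the square orthonormal matrix whose columns are the
    left singular vectors of that mode's unfolding (truncated to the given
    rank if requested); ``core`` links one factor column per mode.
    """

    core: np.ndarray
    factors: dict[str, np.ndarray]
    mode_names: tuple[str, ...]
    gene_mode: str
    mode_labels: dict[str, tuple[str, ...]]

    def factor_column(self, mode: str, l: int) -> np.ndarray:
        """Column l (1-based) of the factor matrix for `mode`."""
        f = self.factors[mode]
        if not 1 <= l <= f.shape[1]:
            raise IndexError(f"component {l} out of range 1..{f.shape[1]} for mode {mode!r}")
        return f[:, l - 1]

    def reconstruct(self) -> np.ndarray:
        out = self.core
        for axis, mode in enumerate(self.mode_names):
            out = np.moveaxis(
                np.tensordot(self.factors[mode], out, axes=(1, axis)), 0, axis
            )
        return out


def hosvd(tensor: ExpressionTensor, rank: Mapping[str, int] | None = None) -> HOSVDResult:
    """Higher-order SVD via SVD of every mode unfolding.

    Each mode's factor matrix holds the left singular vectors of that mode's
    unfolding (sign-fixed).  The core is the tensor contracted with every
    factor's transpose; at full rank (the default) reconstruction is exact
    and distinct core slices along any mode are mutually orthogonal.

    Parameters
    ----------
    tensor
        Input tensor, at least two modes.
    rank
        Optional per-mode truncation ranks; modes not listed keep full rank.
    """
    rank = dict(rank or {})
    factors: dict[str, np.ndarray] = {}
    for mode in tensor.mode_names:
        axis = tensor.axis(mode)
        unf = _unfold_array(tensor.values, axis)
        u, _, _ = np.linalg.svd(unf, full_matrices=True)
        keep = rank.get(mode, u.shape[1])
        if not 1 <= keep <= u.shape[1]:
            raise ValueError(f"rank for mode {mode!r} out of range")
        u = u[:, :keep]
        factors[mode] = u * _sign_fix_columns(u)
    core = tensor.values
    for axis, mode in enumerate(tensor.mode_names):
        core = np.moveaxis(np.tensordot(factors[mode].T, core, axes=(1, axis)), 0, axis)
    return HOSVDResult(
        core=core,
        factors=factors,
        mode_names=tensor.mode_names,
        gene_mode=tensor.gene_mode,
        mode_labels=dict(tensor.mode_labels),
    )


def factor_product_vector(result: HOSVDResult, mode_indices: Mapping[str, int]) -> np.ndarray:
    """Outer product of chosen sample-structure factor columns, flattened.

    For a gene x (sample-structure) tensor this returns the vector with
    entries ``u_{l1 j} * u_{l2 k} * ...`` over all sample-structure cells,
    flattened in the same cell order as :func:`unfold` on the gene mode.
    One 1-based component index per non-gene mode is required.
    """
    rest = [m for m in result.mode_names if m != result.gene_mode]
    missing = [m for m in rest if m not in mode_indices]
    if missing:
        raise KeyError(f"missing component index for mode(s): {missing}")
    columns = [result.factor_column(m, mode_indices[m]) for m in rest]
    grid = columns[0]
    for col in columns[1:]:
        grid = np.multiply.outer(grid, col)
    return grid.reshape(-1)
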