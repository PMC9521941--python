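"""Projection-pursuit selection: class-design vectors and projections onto them.

Instead of letting the decomposition discover the sample structure, projection
pursuit (PP) fixes a design vector ``y`` over samples and scores feature i by
the linear projection ``b_i = sum_j x_ij y_j``.  For a two-class design with
``M_N`` normals followed by ``M_T`` tumors,

    y_j = -M/M_N  (j <= M_N),    y_j = +M/M_T  (j > M_N),    M = M_N + M_T,

which sums to zero.  For the infection tensor the design factorizes over the
sample-structure modes, ``y_jkm = alpha_j beta_k gamma_m`` with
``alpha_j = gamma_m = 1`` and ``beta_k = (-1)^k`` — i.e. the sign alternates
with treatment only.  Any positive rescaling of ``y`` leaves the chi-square
P-values invariant because the estimated sigma rescales identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, ExpressionTensor
from .decomposition import _unfold_array

__all__ = ["LabelVector", "class_label_vector", "tensor_label", "project"]


@dataclass(frozen=True)
class LabelVector:
    """Design vector over samples or sample-structure cells."""

    values: np.ndarray
    class_sizes: tuple[int, int] | None = None


def class_label_vector(n_normal: int, n_tumor: int) -> LabelVector:
    """Zero-sum two-class design: normals first, tumors second."""
    if n_normal < 1 or n_tumor < 1:
        raise ValueError("both class sizes must be at least 1")
    m = n_normal + n_tumor
    y = np.concatenate(
        [np.full(n_normal, -m / n_normal), np.full(n_tumor, m / n_tumor)]
    )
    return LabelVector(values=y, class_sizes=(n_normal, n_tumor))


def tensor_label(n_cell_lines: int, n_treatments: int, n_replicates: int) -> LabelVector:
    """Treatment-contrast design ``y_jkm = (-1)^k`` flattened in unfold order.

    Modes are ordered (cell line, treatment, replicate) with the replicate
    varying fastest, matching :func:`tdfe.decomposition.unfold` on the gene
    mode of a gene x cell-line x treatment x replicate tensor.  k is 1-based,
    so the first treatment level (infected) gets -1 and the second (control)
    gets +1.
    """
    if n_treatments != 2:
        raise ValueError("the treatment contrast requires exactly two treatment levels")
    beta = np.array([(-1.0) ** k for k in range(1, n_treatments + 1)])
    y = np.ones(n_cell_lines)[:, None, None] * beta[None, :, None] * np.ones(n_replicates)[None, None, :]
    return LabelVector(values=y.reshape(-1))


def project(data: ExpressionMatrix | ExpressionTensor, y: LabelVector | np.ndarray) -> np.ndarray:
    """Per-feature projection ``b_i = sum_j x_ij y_j``.

    Tensors are unfolded on the gene mode first, so ``y`` runs over
    sample-structure cells in unfold order.
    """
    yv = y.values if isinstance(y, LabelVector) else np.asarray(y, dtype=float)
    if isinstance(data, ExpressionTensor):
        x = _unfold_array(data.values, data.axis(data.gene_mode))
    else:
        x = data.values
    if yv.shape[0] != x.shape[1]:
        raise ValueError(
            f"design vector length {yv.shape[0]} does not match {x.shape[1]} sample cells"
        )
    return x @ yv
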