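"""End-to-end feature-extraction pipelines composing the lower-level modules.

Each pipeline turns an expression matrix or tensor into a
:class:`~tdfe.selection.FeatureScore`:

* :func:`matrix_fe` — PCA/SVD-based unsupervised FE: standardize, decompose,
  pick the sample-mode singular vector most aligned with the design of
  interest, and score features by the paired gene-mode vector under the
  chi-square Gaussian null.
* :func:`tensor_fe` — TD-based unsupervised FE: HOSVD, pick one factor
  column per sample-structure mode (the treatment-contrast column for the
  treatment mode, the leading column elsewhere), locate the gene-mode
  component with the largest-magnitude core entry against that choice, and
  score features by that gene-mode factor.
* :func:`projection_fe` — projection pursuit: score features by the linear
  projection onto an explicit design vector.
* :func:`shuffling_fe` — like matrix/tensor FE but with empirical P-values
  from a gene-order shuffling null instead of the chi-square assumption
  (conventionally thresholded at adjusted P < 0.1 rather than 0.01).
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, ExpressionTensor, standardize
from .decomposition import HOSVDResult, hosvd, svd
from .nullmodel import empirical_pvalues, shuffle_null
from .projection import LabelVector, project
from .selection import FeatureScore, score_features

__all__ = [
    "pick_component",
    "matrix_fe",
    "tensor_fe",
    "tensor_component_indices",
    "projection_fe",
    "shuffling_fe",
]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return 0.0 if denom == 0 else float(a @ b / denom)


def pick_component(sample_vectors: np.ndarray, design: np.ndarray) -> int:
    """1-based index of the sample-mode vector best aligned with `design`.

    Alignment is the absolute uncentered cosine: for zero-sum designs this
    measures the contrast directly, and (unlike Pearson correlation) it stays
    meaningful for two-level modes, where every centered 2-vector is
    trivially +-1-correlated with the contrast.
    """
    cosines = [abs(_cosine(sample_vectors[:, j], design)) for j in range(sample_vectors.shape[1])]
    return int(np.argmax(cosines)) + 1


def matrix_fe(
    matrix: ExpressionMatrix,
    design: LabelVector | np.ndarray,
    threshold: float = 0.01,
    standardize_first: bool = True,
) -> tuple[FeatureScore, int]:
    """PCA-based unsupervised FE against a sample design of interest.

    Returns the feature scores and the chosen 1-based component index.
    """
    if standardize_first and not matrix.standardized:
        matrix = standardize(matrix)
    y = design.values if isinstance(design, LabelVector) else np.asarray(design, float)
    res = svd(matrix)
    l = pick_component(res.sample_vectors, y)
    scores = score_features(matrix.feature_ids, res.component(l, axis="feature"), threshold)
    return scores, l


def tensor_component_indices(
    result: HOSVDResult,
    treatment_mode: str,
    contrast: np.ndarray | None = None,
) -> dict[str, int]:
    """Choose one factor column per sample-structure mode.

    The treatment mode gets the column most correlated with the two-level
    contrast (default alternating -1/+1); every other sample-structure mode
    gets its leading column, which captures the structure shared across that
    mode's levels.
    """
    sizes = dict(zip(result.mode_names, result.core.shape))
    if contrast is None:
        contrast = np.array([(-1.0) ** k for k in range(1, sizes[treatment_mode] + 1)])
    indices: dict[str, int] = {}
    for mode in result.mode_names:
        if mode == result.gene_mode:
            continue
        if mode == treatment_mode:
            indices[mode] = pick_component(result.factors[mode], contrast)
        else:
            indices[mode] = 1
    return indices


def tensor_fe(
    tensor: ExpressionTensor,
    treatment_mode: str = "treatment",
    threshold: float = 0.01,
) -> tuple[FeatureScore, int, dict[str, int]]:
    """TD-based unsupervised FE on a gene x sample-structure tensor.

    Returns (scores, gene-mode component index, sample-structure indices).
    The gene-mode component is the one whose core entry against the chosen
    sample-structure columns has the largest magnitude.
    """
    result = hosvd(tensor)
    indices = tensor_component_indices(result, treatment_mode)
    slicer: list[int | slice] = [
        slice(None) if m == tensor.gene_mode else indices[m] - 1 for m in tensor.mode_names
    ]
    core_line = result.core[tuple(slicer)]
    l_gene = int(np.argmax(np.abs(core_line))) + 1
    scores = score_features(
        tensor.labels_for(tensor.gene_mode),
        result.factor_column(tensor.gene_mode, l_gene),
        threshold,
    )
    return scores, l_gene, indices


def projection_fe(
    data: ExpressionMatrix | ExpressionTensor,
    design: LabelVector | np.ndarray,
    threshold: float = 0.01,
    standardize_first: bool = True,
) -> FeatureScore:
    """Projection-pursuit FE: score features by b_i = sum_j x_ij y_j."""
    if isinstance(data, ExpressionMatrix) and standardize_first and not data.standardized:
        data = standardize(data)
    b = project(data, design)
    ids = (
        data.labels_for(data.gene_mode)
        if isinstance(data, ExpressionTensor)
        else data.feature_ids
    )
    return score_features(ids, b, threshold)


def shuffling_fe(
    data: ExpressionMatrix | ExpressionTensor,
    l: int,
    observed: np.ndarray,
    threshold: float = 0.1,
    n_shuffles: int = 100,
    seed: int = 0,
) -> FeatureScore:
    """Empirical-null FE: P-values for `observed` from a gene-order shuffling null.

    `l` is the 1-based component harvested from each shuffled decomposition
    (the same index used for the observed analysis).
    """
    null = shuffle_null(data, l, n_shuffles=n_shuffles, seed=seed)
    ids = (
        data.labels_for(data.gene_mode)
        if isinstance(data, ExpressionTensor)
        else data.feature_ids
    )
    raw = empirical_pvalues(observed, null)
    return score_features(ids, np.asarray(observed, float), threshold, raw_p=raw)
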