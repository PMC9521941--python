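"""Labeled containers for expression matrices and multi-mode expression tensors.

An :class:`ExpressionMatrix` is a feature-by-sample real matrix with string
identifiers on both axes.  Standardization here follows the convention used by
unsupervised feature extraction: each *sample column* is centered and scaled
over features so that ``sum_i x_ij = 0`` and ``sum_i x_ij**2 = N``.  This is
deliberately not the per-feature z-scoring common elsewhere: P-values are later
attributed to features from the components of singular vectors, so it is the
per-sample distribution over features that must be placed on a common scale.

An :class:`ExpressionTensor` is a labeled dense array with one designated gene
mode plus one or more sample-structure modes (cell line, treatment,
replicate, ...).  Modes are addressed by name throughout, never by subscript
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionTensor",
    "PairedOmics",
    "standardize",
]


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Feature x sample expression matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_features, n_samples)``; no missing values.
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    standardized
        True once each sample column satisfies ``sum_i x_ij = 0`` and
        ``sum_i x_ij**2 = N``.
    """

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("matrix must have at least one feature and one sample")
        if not np.isfinite(values).all():
            raise ValueError("matrix contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", _check_unique(self.feature_ids, "feature"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        if len(self.feature_ids) != values.shape[0]:
            raise ValueError("feature_ids length does not match number of rows")
        if len(self.sample_ids) != values.shape[1]:
            raise ValueError("sample_ids length does not match number of columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, standardized: bool = False) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            feature_ids=tuple(map(str, frame.index)),
            sample_ids=tuple(map(str, frame.columns)),
            standardized=standardized,
        )

    def subset_features(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        ids = np.asarray(self.feature_ids, dtype=object)[keep]
        return ExpressionMatrix(self.values[keep], tuple(ids), self.sample_ids, self.standardized)


def standardize(matrix: ExpressionMatrix, tol: float = 1e-12) -> ExpressionMatrix:
    """Center and scale every sample column over features.

    Each column j is transformed to satisfy ``sum_i x_ij = 0`` and
    ``sum_i x_ij**2 = N`` (population variance 1 over the N features).
    Idempotent on already-standardized input.

    Raises
    ------
    ValueError
        If any sample column is constant across features (zero variance);
        the offending sample identifier is named.
    """
    x = matrix.values
    n = matrix.n_features
    centered = x - x.mean(axis=0, keepdims=True)
    ss = (centered**2).sum(axis=0)
    bad = np.flatnonzero(ss <= tol * max(n, 1))
    if bad.size:
        raise ValueError(
            f"zero variance in sample column(s): {', '.join(matrix.sample_ids[j] for j in bad)}"
        )
    scaled = centered * np.sqrt(n / ss)
    return replace(matrix, values=scaled, standardized=True)


@dataclass(frozen=True)
class ExpressionTensor:
    """Dense labeled expression tensor with a designated gene mode.

    ``mode_names`` gives one name per axis of ``values``; ``gene_mode`` must be
    one of them.  ``mode_labels`` optionally carries identifiers along each
    mode (the gene mode's labels double as feature ids).
    """

    values: np.ndarray
    mode_names: tuple[str, ...]
    gene_mode: str = "gene"
    mode_labels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim < 2:
            raise ValueError("tensor must have at least two modes")
        if any(s == 0 for s in values.shape):
            raise ValueError("tensor has a mode of size zero")
        if not np.isfinite(values).all():
            raise ValueError("tensor contains non-finite values")
        names = tuple(self.mode_names)
        if len(names) != values.ndim:
            raise ValueError("mode_names length does not match tensor order")
        if len(set(names)) != len(names):
            raise ValueError("mode names must be unique")
        if self.gene_mode not in names:
            raise ValueError(f"gene mode {self.gene_mode!r} not among modes {names}")
        labels = dict(self.mode_labels)
        for name, labs in labels.items():
            if name not in names:
                raise ValueError(f"labels given for unknown mode {name!r}")
            if len(labs) != values.shape[names.index(name)]:
                raise ValueError(f"label count mismatch on mode {name!r}")
            labels[name] = tuple(map(str, labs))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mode_names", names)
        object.__setattr__(self, "mode_labels", labels)

    @property
    def mode_sizes(self) -> dict[str, int]:
        return dict(zip(self.mode_names, self.values.shape))

    def axis(self, mode: str) -> int:
        try:
            return self.mode_names.index(mode)
        except ValueError:
            raise KeyError(f"unknown mode {mode!r}; modes are {self.mode_names}") from None

    def labels_for(self, mode: str) -> tuple[str, ...]:
        if mode in self.mode_labels:
            return self.mode_labels[mode]
        return tuple(f"{mode}{i}" for i in range(self.mode_sizes[mode]))


@dataclass(frozen=True)
class PairedOmics:
    """Two expression matrices (e.g. mRNA and miRNA) over identical samples."""

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.mrna.sample_ids != self.mirna.sample_ids:
            raise ValueError("paired matrices must share identical sample_ids in the same order")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.mrna.sample_ids
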