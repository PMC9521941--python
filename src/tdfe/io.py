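"""TSV/JSON readers and writers for matrices, tensors, and labels.

Matrix TSV: first column feature id, header row sample ids, tab-separated
floats.  Tensor long TSV: one row per cell with one column per mode label
plus a ``value`` column, accompanied by a sidecar JSON naming the modes,
their order, the gene mode, and per-mode labels.  Labels TSV: two columns,
``sample_id`` and ``class``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ExpressionTensor

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_tensor_tsv",
    "write_tensor_tsv",
    "read_labels_tsv",
]


def read_matrix_tsv(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(frame)


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("feature_id").to_csv(path, sep="\t")


def write_tensor_tsv(tensor: ExpressionTensor, path: str | Path) -> None:
    """Write long-format TSV plus a ``<path>.modes.json`` sidecar."""
    path = Path(path)
    idx = pd.MultiIndex.from_product(
        [tensor.labels_for(m) for m in tensor.mode_names], names=list(tensor.mode_names)
    )
    frame = pd.DataFrame({"value": tensor.values.reshape(-1)}, index=idx).reset_index()
    frame.to_csv(path, sep="\t", index=False)
    sidecar = {
        "mode_names": list(tensor.mode_names),
        "gene_mode": tensor.gene_mode,
        "mode_labels": {m: list(tensor.labels_for(m)) for m in tensor.mode_names},
    }
    Path(str(path) + ".modes.json").write_text(json.dumps(sidecar, indent=1))


def read_tensor_tsv(path: str | Path, sidecar: str | Path | None = None) -> ExpressionTensor:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else Path(str(path) + ".modes.json")
    meta = json.loads(sidecar.read_text())
    mode_names = list(meta["mode_names"])
    labels = {m: list(v) for m, v in meta["mode_labels"].items()}
    frame = pd.read_csv(path, sep="\t", dtype={m: str for m in mode_names})
    shape = tuple(len(labels[m]) for m in mode_names)
    values = np.full(shape, np.nan)
    indexers = [
        pd.Categorical(frame[m], categories=labels[m]).codes for m in mode_names
    ]
    if any((idx < 0).any() for idx in indexers):
        raise ValueError("tensor TSV contains labels absent from the sidecar")
    values[tuple(indexers)] = frame["value"].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("tensor TSV does not cover every cell")
    return ExpressionTensor(
        values,
        mode_names=tuple(mode_names),
        gene_mode=meta["gene_mode"],
        mode_labels={m: tuple(v) for m, v in labels.items()},
    )


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Sample-to-class mapping; columns ``sample_id`` and ``class``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "class"} <= set(frame.columns):
        raise ValueError("labels TSV needs columns 'sample_id' and 'class'")
    return frame.set_index("sample_id")["class"]
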