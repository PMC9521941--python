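"""Seeded generators emulating the statistical structure of the study designs.

Three designs are covered, mirroring the shapes in which the method is used
in practice:

* a two-class feature x sample matrix (tumor vs. normal) with a small set of
  planted differentially expressed features whose class-mean difference is a
  chosen multiple of the noise standard deviation;
* a paired mRNA/miRNA matrix pair sharing their sample-mode singular vectors
  (the condition under which the integrated product-matrix SVD exactly
  recovers both feature factor sets);
* a gene x cell-line x treatment x replicate infection tensor (default mode
  sizes 5 x 2 x 3) whose planted genes respond with opposite signs across the
  two treatment levels, uniformly over cell lines and replicates.

Every generator is a pure function of its spec (seed included); Gaussian
noise is the default, with a lognormal option to exercise the realistic case
where expression is far from Gaussian.  Effect sizes are parameterized in
units of the noise standard deviation so downstream thresholds are
scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, ExpressionTensor, PairedOmics

__all__ = [
    "SyntheticSpec",
    "make_two_class_matrix",
    "make_paired_omics",
    "make_infection_tensor",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic expression data set.

    ``effect`` is the between-class mean shift of planted features in units
    of the noise standard deviation.  ``class_sizes`` applies to two-class
    matrices, ``mode_sizes`` (cell lines, treatments, replicates) to the
    infection tensor.
    """

    n_features: int = 2000
    class_sizes: tuple[int, int] = (20, 20)
    mode_sizes: tuple[int, int, int] = (5, 2, 3)
    n_deg: int = 20
    effect: float = 10.0
    noise_model: str = "gaussian"
    seed: int = 0
    n_mirna: int = 200

    def __post_init__(self) -> None:
        if self.n_deg > self.n_features:
            raise ValueError("n_deg cannot exceed n_features")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError("noise_model must be 'gaussian' or 'lognormal'")


def _noise(rng: np.random.Generator, shape: tuple[int, ...], model: str) -> tuple[np.ndarray, float]:
    """Noise array plus its population SD (unit for effect sizes)."""
    if model == "gaussian":
        return rng.standard_normal(shape), 1.0
    # lognormal exp(N(0,1)): heavy right tail, SD = sqrt((e-1)e)
    sd = float(np.sqrt((np.e - 1.0) * np.e))
    return rng.lognormal(0.0, 1.0, shape), sd


def make_two_class_matrix(spec: SyntheticSpec) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Two-class matrix with planted DEGs; returns (matrix, planted ids).

    Samples are ordered normals first, tumors second.  Each planted feature
    gets a mean shift of ``+-effect/2`` per class (sign drawn per feature, so
    the planted set mixes up- and down-regulation) for a between-class
    difference of ``effect`` noise SDs.
    """
    rng = np.random.default_rng(spec.seed)
    n_n, n_t = spec.class_sizes
    if n_n < 1 or n_t < 1:
        raise ValueError("both class sizes must be at least 1")
    m = n_n + n_t
    x, noise_sd = _noise(rng, (spec.n_features, m), spec.noise_model)
    planted = rng.choice(spec.n_features, size=spec.n_deg, replace=False)
    planted.sort()
    signs = rng.choice([-1.0, 1.0], size=spec.n_deg)
    half = 0.5 * spec.effect * noise_sd
    x[np.ix_(planted, np.arange(n_n))] -= (signs * half)[:, None]
    x[np.ix_(planted, np.arange(n_n, m))] += (signs * half)[:, None]
    feature_ids = tuple(f"gene{i}" for i in range(spec.n_features))
    sample_ids = tuple(
        [f"normal{j}" for j in range(n_n)] + [f"tumor{j}" for j in range(n_t)]
    )
    matrix = ExpressionMatrix(x, feature_ids, sample_ids)
    return matrix, tuple(feature_ids[i] for i in planted)


@dataclass(frozen=True)
class PairedOmicsTruth:
    """Ground-truth factors of a generated paired-omics data set."""

    mrna_factors: np.ndarray  # (N, R) orthonormal columns u_l
    mirna_factors: np.ndarray  # (K, R) orthonormal columns u'_l
    sample_factors: np.ndarray  # (M, R) shared orthonormal columns v_l
    mrna_singular_values: np.ndarray
    mirna_singular_values: np.ndarray


def _random_orthonormal(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return q


def make_paired_omics(
    spec: SyntheticSpec,
    shared_rank: int = 3,
    noise: float = 0.0,
) -> tuple[PairedOmics, PairedOmicsTruth]:
    """Paired matrices sharing sample-mode singular vectors.

    ``X_mrna = sum_l lambda_l u_l v_l^T + E`` and
    ``X_mirna = sum_l lambda'_l u'_l v_l^T + E'`` with a common orthonormal
    sample factor matrix v.  Singular values are well separated
    (lambda_l proportional to shared_rank - l + 1).  ``noise`` is the ratio
    of each noise term's Frobenius norm to its signal's Frobenius norm
    (0.1 = 10% relative noise).
    """
    if shared_rank < 1:
        raise ValueError("shared_rank must be at least 1")
    m = sum(spec.class_sizes)
    n, k = spec.n_features, spec.n_mirna
    if shared_rank > min(n, k, m):
        raise ValueError("shared_rank exceeds the smallest dimension")
    rng = np.random.default_rng(spec.seed)
    u = _random_orthonormal(rng, n, shared_rank)
    up = _random_orthonormal(rng, k, shared_rank)
    v = _random_orthonormal(rng, m, shared_rank)
    lam = 10.0 * np.arange(shared_rank, 0, -1, dtype=float)
    lamp = 8.0 * np.arange(shared_rank, 0, -1, dtype=float)
    x_mrna = (u * lam) @ v.T
    x_mirna = (up * lamp) @ v.T
    if noise > 0:
        for x, sig in ((x_mrna, lam), (x_mirna, lamp)):
            e = rng.standard_normal(x.shape)
            e *= noise * np.sqrt((sig**2).sum()) / np.linalg.norm(e)
            x += e
    sample_ids = tuple(f"s{j}" for j in range(m))
    pair = PairedOmics(
        mrna=ExpressionMatrix(x_mrna, tuple(f"mrna{i}" for i in range(n)), sample_ids),
        mirna=ExpressionMatrix(x_mirna, tuple(f"mirna{i}" for i in range(k)), sample_ids),
    )
    truth = PairedOmicsTruth(u, up, v, lam, lamp)
    return pair, truth


def make_infection_tensor(spec: SyntheticSpec) -> tuple[ExpressionTensor, tuple[str, ...]]:
    """Gene x cell-line x treatment x replicate tensor with planted responders.

    Planted genes carry a mean of ``+-effect/2 * (-1)^k`` (k the 1-based
    treatment level, sign drawn per gene): opposite signs between infected
    (k=1) and control (k=2), constant across cell lines and replicates.
    Other genes are pure noise.
    """
    n_cl, n_tr, n_rep = spec.mode_sizes
    if n_tr != 2:
        raise ValueError("the infection design requires exactly two treatment levels")
    rng = np.random.default_rng(spec.seed)
    x, noise_sd = _noise(rng, (spec.n_features, n_cl, n_tr, n_rep), spec.noise_model)
    planted = rng.choice(spec.n_features, size=spec.n_deg, replace=False)
    planted.sort()
    signs = rng.choice([-1.0, 1.0], size=spec.n_deg)
    beta = np.array([(-1.0) ** k for k in range(1, n_tr + 1)])  # (-1, +1)
    shift = 0.5 * spec.effect * noise_sd * signs[:, None] * beta[None, :]
    x[planted] += shift[:, None, :, None]
    gene_ids = tuple(f"gene{i}" for i in range(spec.n_features))
    tensor = ExpressionTensor(
        x,
        mode_names=("gene", "cell_line", "treatment", "replicate"),
        gene_mode="gene",
        mode_labels={
            "gene": gene_ids,
            "cell_line": tuple(f"cl{j}" for j in range(n_cl)),
            "treatment": ("infected", "control"),
            "replicate": tuple(f"rep{r}" for r in range(n_rep)),
        },
    )
    return tensor, tuple(gene_ids[i] for i in planted)
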