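# Methods

## Model and procedure

The package implements unsupervised feature extraction (FE) by matrix and
tensor decomposition, plus the three analyses that justify it.

**Standardization.** Each *sample column* of the feature × sample matrix is
centered and scaled over features to ∑ᵢ xᵢⱼ = 0, ∑ᵢ xᵢⱼ² = N. This is the
convention required when P-values are attributed to features from
singular-vector components; it is intentionally not per-feature z-scoring.
Columns with zero variance across features are rejected by name.

**SVD/PCA.** The decomposition xᵢⱼ = ∑_ℓ λ_ℓ u_ℓᵢ v_ℓⱼ is stored with the
singular values λ_ℓ; the gram-matrix eigenproblems X Xᵀ u = λ² u and
Xᵀ X v = λ² v then hold with the *squared* singular value as eigenvalue, and
v_ℓ = Xᵀ u_ℓ / λ_ℓ. (Formulations that write the same symbol for the
gram-matrix eigenvalue and the expansion coefficient are internally
inconsistent; storing singular values makes every identity exact.)

**Sign convention.** Each factor column is flipped so its largest-magnitude
entry is positive, with the flip propagated to the paired factor (SVD) or
absorbed by the core (HOSVD). Decompositions are therefore deterministic
functions of the input. The convention leaves a small positive bias in the
mean of pooled null singular-vector components; the empirical P-value is
two-sided in |z| and unaffected.

**HOSVD.** Per-mode factors are the left singular vectors of each mode's
unfolding; the core is the tensor contracted with every factor transpose.
Unfolding places the chosen mode on rows and enumerates the remaining modes
in their original order with the *last-listed mode varying fastest* — fixed
and documented here because multiple conventions exist. Full square factors
are computed by default (desk-scale tensors); per-mode truncation is an
option flag. Modes are addressed by name throughout, never by subscript
position, to avoid any dependence on mode ordering conventions.

**Feature scoring.** P_i = P_χ²[> (score_i/σ)²] with df = 1 — the only
degrees-of-freedom choice consistent with a single squared standardized
Gaussian score. σ is the population SD (ddof = 0) of the whole score vector,
no trimming, no iteration. BH adjustment; selection strictly below the
threshold (default 0.01).

**Component choice.** The sample-mode vector "of interest" is chosen by
maximal absolute *uncentered* cosine with the design vector. Pearson
correlation is wrong for two-level modes: after centering, every 2-vector is
±1-correlated with the contrast, making the choice a coin flip. For the
tensor pipeline, the treatment mode gets the contrast-aligned column, other
sample-structure modes their leading column, and the gene-mode component is
the one with the largest |core| entry against that combination.

**Integration.** x_ik = ∑ⱼ x_ij x_kj is computed as X_mrna X_mirnaᵀ; the
three-mode product tensor is never materialized (for genome-scale N·M·K it
cannot be). Both matrices are standardized first by default (flag to
disable), for consistency with the FE pipeline that consumes the factors.
Factor pairing against per-matrix SVDs uses greedy matching by absolute
cosine similarity.

**Shuffling null.** For each of n_shuffles (default 100) iterations the gene
index is permuted independently within every sample column (or every
sample-structure cell of the gene-mode unfolding — the gene-mode HOSVD
factors equal the unfolding's left singular vectors, so only an economy SVD
is re-run per shuffle), the decomposition is recomputed, and the components
of the *same* 1-based vector index as the observed analysis are pooled.
Pooling is across shuffles and features; the empirical P-value is two-sided
with the +1 correction, P = (1 + #{|z| ≥ |obs|})/(1 + pool), the standard
permutation estimator (the formula is otherwise underdetermined; per-shuffle
extremes would be the conservative alternative and are not implemented).
A single seeded generator drives all permutations sequentially, so pools are
bit-reproducible. Low-expression filtering (top-n by ∑ⱼ|xᵢⱼ|, stable ties)
is applied *before* shuffling when requested; n has no default because it is
a per-dataset judgement call.

**Fisher exact test.** Hand-built in log space: hypergeometric
log-probabilities over the whole same-margin support via log-gamma,
two-sided by the minimum-likelihood rule (sum of probabilities ≤ observed,
with a 1e-7 relative tolerance on the probability scale, matching R's
`fisher.test`). Needed because the concordance tables of interest produce
P-values at 1e-100–1e-300 scales where naive products underflow. Sidedness
is not settled by convention in this literature; two-sided minlike is the
dominant one and is used throughout.

**K-means equivalence.** Tr S_b is computed as ∑ₛ ‖X h_s‖² in the
M-dimensional sample space (never the N × N scatter matrix). The
centroid-subspace comparison centers columns about the grand mean (the
equivalence is a statement about centered data), runs K-means (scikit-learn,
Lloyd, random init, 10 restarts), and reports principal angles between
span{X h_s} and span{u₁…u_{S−1}}. With spherical noise and no clusters the
angles are unconstrained — that negative control is documented, not
asserted.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical geometry* the method exploits:
a low-rank class contrast on top of i.i.d. noise (two-class matrix), shared
sample-mode singular vectors across two omics layers (paired matrices), and
a treatment-mode contrast constant over cell lines and replicates
(infection tensor, default 5 × 2 × 3). Defaults: N = 2000 features, 20
planted DEGs, 20 + 20 samples, effect 10 noise-SD — a strong-signal regime
where recovery should be essentially perfect, so deviations indicate bugs
rather than statistical bad luck. Effects are parameterized in noise-SD
units; Gaussian noise is the default because the χ² null assumes it, and a
lognormal option exercises the realistic heavy-tailed case.

Not emulated: count-based mean–variance structure (negative binomial
library-size models), correlated genes, batch effects, or the unbalanced
class sizes of real cohorts. Passing tests on this data shows the
*algebra and pipelines* are correct and that the method behaves as claimed
under its own assumptions — not that it will select biologically meaningful
genes on any particular real data set.

## Numerical choices

* Orthonormality/reconstruction tolerances: 1e−8 relative; identities
  asserted at machine precision use 1e−10–1e−13.
* BH adjustment delegated to statsmodels; K-means to scikit-learn; χ²
  survival function to scipy. The Fisher exact test and HOSVD are authored
  here (the log-space regime and the mode-named tensor algebra are the point).
* Empirical P-values use searchsorted on the sorted |pool| — O((P+F) log P).
* Low-expression ranking ties: stable, input order.
* Degenerate inputs (constant columns, zero-size modes, empty pools,
  out-of-range component indices) raise ValueError/KeyError with the
  offending identifier where applicable.

## Acceptance-script problem sizes

The acceptance script runs at the generator defaults (N = 2000 matrix
pipelines, N = 1000 paired integration, N = 500 tensor, 100 shuffles),
completing in well under a minute; these sizes were chosen as the smallest
at which the strong-signal regime and the pooled-null resolution
(pool ≈ 2 × 10⁵) are comfortably achieved.

## Known limitations

* The bundled published concordance tables include two whose printed Fisher
  P-values are inconsistent with their own printed cell counts (flagged in
  `tdfe.datasets.CONSISTENT_WITH_CELLS`); recomputation from the cells is
  authoritative here.
* The integrated-analysis factor recovery is exact only when the two
  matrices share sample-mode singular vectors; no error bound is asserted
  for the approximate case.
* The shuffling-null pipeline's 0.01 ↔ 0.1 threshold correspondence is an
  empirical regularity, demonstrated on synthetic data at desk scale, not a
  theorem.
* K-means-based comparisons inherit K-means' weaknesses on unbalanced
  clusters; the selection pipelines themselves do not use K-means.
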