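# tdfe — PCA/tensor-decomposition unsupervised feature extraction

`tdfe` selects differentially expressed features (genes, mRNAs, miRNAs) from
expression matrices and multi-mode expression tensors by the magnitude of
their singular-vector components, and provides the machinery to rationalize
why that works: a projection-pursuit view, a K-means centroid-subspace
equivalence, and an assumption-free gene-order shuffling null.

It is aimed at transcriptomics practitioners facing the classic *N ≫ M*
problem — tens of thousands of genes, a handful of samples — where
statistical-test feature selection is dominated by sample-size effects.

## The method

Given a feature × sample matrix *X* ∈ ℝ^(N×M), each sample column is
standardized over features (∑ᵢ xᵢⱼ = 0, ∑ᵢ xᵢⱼ² = N) and decomposed as
*x*ᵢⱼ = ∑_ℓ λ_ℓ u_ℓᵢ v_ℓⱼ. The sample-mode vector **v**_ℓ of interest (e.g.
the one aligned with a tumor/normal contrast) is identified; features are
then scored by the paired gene-mode components u_ℓᵢ under the working null
that they are Gaussian:

    Pᵢ = P_χ²[ > (u_ℓᵢ / σ_ℓ)² ]   (df = 1, σ_ℓ the population SD of u_ℓ)

followed by Benjamini–Hochberg adjustment and selection at adjusted
P < 0.01. For a gene × cell-line × treatment × replicate tensor the same
logic runs through the HOSVD: per-mode factors are the left singular vectors
of each mode's unfolding, the core tensor identifies which gene-mode vector
pairs with the sample-structure factors of interest, and that vector is
scored the same way.

Three rationalizations are implemented alongside:

* **Projection pursuit** — scoring features by bᵢ = ∑ⱼ xᵢⱼ yⱼ for an explicit
  class-design vector **y** selects nearly the same features; on exactly
  rank-structured data with **y** = **v**_ℓ the two statistics are identical
  up to scale.
* **K-means equivalence** — the subspace spanned by optimal cluster
  centroids coincides (principal angles ≈ 0) with the span of the leading
  PC score vectors, so the unsupervised decomposition finds the cluster
  structure a supervised design would encode.
* **Shuffling null** — permuting the gene order independently within each
  sample and re-decomposing yields an empirical null for u_ℓᵢ; adjusted
  P < 0.1 under this null empirically selects the features the Gaussian
  χ² pipeline selects at adjusted P < 0.01.

Integrated mRNA × miRNA analysis goes through the sample-collapsed product
matrix x_ik = ∑ⱼ x_ij x_kj (computed as a single matrix product — the
N × M × K product tensor is never materialized), whose SVD recovers both
feature factor sets exactly when the two matrices share sample-mode singular
vectors.

## Worked example

```python
from tdfe import (SyntheticSpec, make_two_class_matrix, class_label_vector,
                  matrix_fe, projection_fe, confusion)

spec = SyntheticSpec(n_features=2000, n_deg=20, effect=10.0,
                     class_sizes=(20, 20), seed=1)
matrix, planted = make_two_class_matrix(spec)
design = class_label_vector(20, 20)

scores, l = matrix_fe(matrix, design, threshold=0.01)
print(f"component used: {l}")
print(f"selected {len(scores.selected_ids)} of {spec.n_features} features")

pp_scores = projection_fe(matrix, design, threshold=0.01)
table = confusion(scores.selected_ids, pp_scores.selected_ids, matrix.feature_ids)
print("confusion counts:", table.counts.tolist())
print(f"Fisher exact P = {table.fisher_p:.3e}")
```

Output:

```
component used: 1
selected 20 of 2000 features
confusion counts: [[1980, 0], [0, 20]]
Fisher exact P = 2.552e-48
```

All 20 planted differentially expressed features are recovered with no false
positives, the projection-pursuit selection agrees perfectly, and the
concordance of the two methods is quantified by a log-space Fisher exact
test (stable down to P ≈ 10⁻³⁰⁰, far past where naive hypergeometric
products underflow).

The same workflow is available from a shell:

```sh
tdfe simulate two-class --seed 1 --out data/
tdfe select  --input data/matrix.tsv --labels data/labels.tsv --out sel_td.tsv
tdfe project --input data/matrix.tsv --labels data/labels.tsv --out sel_pp.tsv
tdfe compare --a sel_td.tsv --b sel_pp.tsv --out table.json
```

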