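# wonparafac

Weighted orthogonal non-negative PARAFAC (WON-PARAFAC) for integrating
mutation, copy-number and gene-expression data across a panel of samples
(cancer cell lines, patient-derived xenografts), with the downstream
machinery such a factorization needs: rank selection, factor enrichment
against tissue types and gene sets, elastic-net drug-response prediction
on factor loadings, and projection of an independent cohort onto fixed
factors.

## The model

The data are organized as a non-negative three-way array (a *data cube*)
**X** of shape genes × samples × data types.  Mixed-sign data types
(z-scored expression, ternarized copy number) are split by sign into
separate non-negative layers — GE(+), GE(−), CN(+), CN(−) — and stacked
with the binary mutation layer MT.  The cube is factorized as a sum of
*k* rank-1 tensors,

    X[i,j,l]  ≈  Σ_r  G[i,r] · C[j,r] · D[l,r],      G, C, D ≥ 0,

where **G** (genes × k) holds the gene-factors, **C** (samples × k) the
cell-factors, and **D** (data types × k) the DT-factors.  Each factor is
a sparse, interpretable module: a set of genes, the samples in which the
module is active, and the data types through which it manifests (a
DT-factor spanning, say, CN(+) and GE(+) captures an amplification with
concordant over-expression — a cis-effect).

Fitting minimizes a weighted squared error with per-layer weights
1/‖X_d‖²_F, so that low-variance data types (binary mutations) are not
drowned out by high-variance ones (expression), using multiplicative
alternating updates that preserve non-negativity.  The gene-mode update
additionally blends in the natural-gradient update for the
orthogonality-constrained problem (GᵀG = I on the Stiefel manifold) with
a mixing weight `w` in [0, 1] (default 0.1): the constraint discourages
one gene from loading on many factors and thereby favours factors that
tie the *same* genes together across data types.

Downstream:

* **Rank selection** — scan k, score each fit by a Gaussian-profile AIC
  `n·ln(RSS/n) + 2·k·(g+c+d)` and by the mean pairwise cosine similarity
  of the columns of Y_GD = (D ⊙ G) (factor redundancy).
* **CSEA** — for a sample category T of size n_T, the enrichment score
  `ES = √n_T · mean_T(c_i − m)/σ` is ~N(0,1) under random membership;
  right-tailed p-values with Benjamini–Hochberg FDR, significant at
  FDR < 0.2.
* **GSEA** — genes are ranked per factor by the coefficients of a
  per-gene linear regression of expression on all factor loadings; a
  weighted Kolmogorov–Smirnov running sum (exponent 1) scores each gene
  set, with a null from permuting the expression matrix's samples.
* **Drug response** — per-compound elastic nets on factor loadings, the
  penalty chosen by 10-fold CV, honest performance by nested double-loop
  CV with a fold partition that is a deterministic function of the seed
  (so factor-based and raw-feature models are compared on identical
  folds).  Negative coefficients mark sensitivity factors (lower AUC).
* **Translation** — a second cohort is projected onto frozen **G** and
  **D** by optimizing only its sample-factor matrix **P** ≥ 0, scored
  against a permuted-cube baseline, linked to tissue-associated factors
  by loading shares, and compared with cell lines in 2-D embeddings via
  the Fisher criterion |m₁ − m₂|²/(s₁² + s₂²).

## Worked example

Everything runs on seeded synthetic data with planted structure — no
downloads needed:

```python
import numpy as np
from wonparafac import (SyntheticSpec, make_planted_cube, make_annotations,
                        fit, explained_variation, csea)

spec = SyntheticSpec(seed=1)            # 120 genes x 80 samples x 5 layers, rank 6
cube, truth = make_planted_cube(spec)
model = fit(cube, k=6, w=0.1, seed=1)   # weighted, orthogonality mix w = 0.1

print(f"converged: {model.converged} after {len(model.objective_trace)-1} sweeps")
print(f"explained variation: {explained_variation(cube, model):.3f}")
print(f"factor scales: {np.round(model.scales, 2)}")

tissue, _ = make_annotations(spec, truth)
print(csea(model.C[:, 0], tissue, sample_ids=cube.sample_ids).head(2))
```

prints

```
converged: True after 120 sweeps
explained variation: 0.993
factor scales: [59.04 57.81 40.4  37.67 37.12 33.61]
category   n        es             p           fdr  significant
 tissue1  20  6.683531  1.166266e-11  4.665065e-11         True
 tissue3  20 -1.814640  9.652104e-01  9.951978e-01        False
```

The fitted model explains 99% of the cube's variation at the planted
rank; the leading cell-factor is significantly enriched for the tissue
block it was planted in (ES ≈ 6.7, FDR ≪ 0.2), while unrelated tissues
score near or below zero.

The same pipeline is available from the shell:

```sh
wonparafac simulate --preset planted --seed 1 --out sim/
wonparafac fit --cube sim/ --k 6 --w 0.1 --seed 1 --out model/
wonparafac enrich csea --model model/ --annotation sim/tissues.tsv --out csea.tsv
wonparafac project --model model/ --cube cohort/ --out proj/
```

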