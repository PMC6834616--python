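# Methods

## Cube construction

Each data type arrives as a genes × samples matrix.  Expression is
z-scored per gene (population SD by default — the convention is exposed
as a flag — so the worked unit examples are deterministic); an
independent cohort passes its own per-gene statistics rather than the
training cohort's.  Copy number is reduced to three states: gain (1) for
values strictly above the gain threshold (default 5), loss (−1) at or
below the loss threshold (default 1), neutral (0) otherwise — strict
inequality for gain, non-strict for loss.  Mutation calls are binarized.
Mixed-sign layers are then split by sign into two non-negative layers
(`x ↦ (max(x,0), max(−x,0))`, exactly invertible), giving the canonical
five-layer stack GE(+), GE(−), CN(+), CN(−), MT.  Layers are aligned on
the intersection of gene and sample identifiers (order taken from the
first layer); alternatively a gene present in only some layers can be
kept and zero-filled in the others, flagged in the alignment report.
Zero-variance genes standardize to all-zero rows and are reported, not
dropped, to preserve alignment.

The weight tensor is constant within each layer slab with weight
1/‖X_d‖²_F.  The description of the weighting scheme admits two readings
(mode-wise scalars over the three factor matrices vs per-data-type
scalars); only the per-layer reading yields a weight tensor of the
cube's shape in which low-variance data types receive high weight, so
that is the implementation, with the weights overridable by the caller
(including uniform weights to disable the scheme).

## The factorization

Unfoldings and Khatri–Rao products use one self-consistent convention:
column j of `khatri_rao(A, B)` is `kron(A[:,j], B[:,j])` (A's index
slow, B's fast), and the three matricizations are ordered so that the
model's mode-m unfolding equals the paired Khatri–Rao product times the
mode-m factor transposed.  Any self-consistent convention gives
identical fits; consistency is enforced by property tests rather than by
convention-matching.

Updates are multiplicative: each factor is multiplied elementwise by the
ratio of the negative to the positive part of the gradient of the
weighted least-squares objective, with learning-rate exponent fixed at 1.
For the sample and data-type modes the denominator is the plain weighted
one.  For the gene mode the denominator is a convex mix, with weight
`w`, of the plain denominator and the denominator obtained from the
natural gradient on the Stiefel manifold of the orthogonality-
constrained problem (GᵀG = I); the numerator is the same in both.  At
`w = 0` the update is classical weighted multiplicative NMF per mode
(verified elementwise against scikit-learn's MU solver on a single-layer
cube); at `w = 1` it is the fully constrained update.  The default
`w = 0.1` keeps the reconstruction error close to the unconstrained
optimum while measurably reducing gene-factor overlap; tests assert
objective monotonicity for `w ∈ {0, 0.1}` (for w near 1 the mixed update
is a heuristic and monotonicity is only measured).

Numerical choices: denominators are floored at 1e-12; entries whose
numerator and denominator both vanish stay exactly zero (zero-locking);
random initialization draws i.i.d. uniform(0,1) factors rescaled so the
initial reconstruction matches the cube's Frobenius norm; convergence is
declared when the relative objective change per sweep falls below `tol`
(default 1e-6) or after `max_iter` sweeps (default 500); runs are
bit-reproducible given (init, seed).  After fitting, factor columns are
rescaled to unit l2 norm, the product of the three removed norms becomes
the factor's scale, and factors are sorted by scale (stable sort; all-
zero factors get scale 0, sort last and are flagged).  Normalization
happens once at the end: the update rules as written assume unnormalized
factors.

## Rank selection

Each candidate rank is fitted from a deterministic "eigen"
initialization: the elementwise absolute value of the leading k singular
vectors of each mode's unfolding (the absolute value resolves the sign
ambiguity and guarantees non-negativity).  For the data-type mode, whose
dimension (5) is usually below k, the missing columns are seeded
uniform draws scaled to the magnitude of the available ones.

AIC needs a likelihood, which the least-squares setting does not fix; we
use the Gaussian profile form `AIC = n·ln(RSS/n) + 2p` with `n` the
number of cube entries, RSS the unweighted squared residual and
`p = k(g + c + d)` free parameters.  Redundancy is the mean pairwise
cosine similarity of the columns of Y_GD = (D ⊙ G).  "Low AIC and low
cosine" is not an algorithm, so the selection rule is explicit: the
smallest rank whose AIC lies within 1% (of the scan's AIC spread) of the
minimum and whose mean cosine is below 0.5; if no rank passes the cosine
guard, the plain AIC minimizer.  On planted cubes the AIC minimum lands
at or adjacent to the true rank (acceptance suite).

## Enrichment

CSEA's score formula leaves the meaning of "n" open (category size vs
total sample count).  We use the category size n_T — the only reading
under which the score is asymptotically standard normal under random
membership (variance (N − n_T)/(N − 1) → 1 for n_T ≪ N), which the
stated N(0,1) right-tailed test presupposes.  The literal total-count
reading is available behind `total_n=True` for comparison.  The mean and
SD in the score are population statistics over all loadings.  FDR is
Benjamini–Hochberg across categories within each factor; FDR < 0.2 is
flagged significant.

The factor–expression association regresses each gene's expression on
all k factor loadings jointly (with intercept), returning the k slopes;
a rank-deficient design falls back to a tiny ridge.  The alternative
reading — one simple regression per factor — is available via
`joint=False`.  GSEA uses the original weighted Kolmogorov–Smirnov
running sum with weight exponent 1 on the coefficient-ranked list.  The
null permutes the expression matrix's sample axis and re-runs the
regression (preserving gene–gene correlation), 1000 permutations by
default; normalized scores divide by the same-sign null mean per set,
and the FDR compares pooled null and observed tail fractions, positive
and negative sides separately, per factor.  Note that the extremal-ES
set for the positive side is the top of the *ranking* (largest positive
coefficients): a set assembled by |coefficient| would include strongly
negative genes at the tail of the list, which depress a positive running
sum.

## Drug response

One elastic net per compound (scikit-learn coordinate descent), the
penalty chosen at minimum 10-fold CV loss; the l1/l2 mixing ratio is not
dictated by the procedure and defaults to 0.5, exposed in the API and
recorded in outputs.  Predictors are standardized internally (factor
scales differ by construction) and coefficients are reported back on the
original scale.  Missing responses are dropped per compound, not
imputed.  Honest performance is the Pearson correlation between
concatenated out-of-fold predictions of a nested double-loop CV
(10 outer / 10 inner folds); the outer partition depends only on
(sample count, fold count, seed) so factor-based and raw-feature models
share folds exactly.

A known limitation: the pooled out-of-fold correlation is negatively
biased under the null — held-out values anti-correlate with
training-fold means once the overall sample mean is fixed — with bias of
order 1/√n (about −0.2 at n = 100, −0.02 at n = 4000 in our
simulations).  Null calibration of the statistic is therefore meaningful
only in its large-sample regime, and small-sample null correlations
should be compared against a permutation baseline rather than against
zero.

Factor contributions to a model's predictions are
`mean_i |β_j · x_ij|`, normalized to sum to one over the nonzero
coefficients.  The sensitivity/resistance partition takes the union of
the top five |coefficient| factors, splits them by coefficient sign
(negative = sensitivity, since lower AUC means more sensitive), and
assigns each sample by comparing its summed loadings on the two sides;
ties go to the resistant side by default (configurable, counted in the
output).

## Translation to a second cohort

Projection freezes G and D (with the per-factor scales folded into the
design matrix Y_GD so the new loadings are on the same scale as the
training cell-factors) and iterates the sample-mode multiplicative
update on P ≥ 0 under uniform weights — the projection objective is the
plain Frobenius loss.  P is initialized from seeded uniform draws scaled
to the cohort norm.  Per-sample explained variation is
1 − ‖residual fiber‖²/‖data fiber‖².  The permuted baseline permutes
gene and sample indices independently *within each layer* (destroying
cross-layer as well as factor structure while preserving each layer's
value distribution) and projects the permuted cube.

The Fisher criterion between two groups of embedded points is
‖m₁ − m₂‖²/(s₁² + s₂²) with population variances and each group's
variance taken as the trace of its covariance; it is exactly invariant
under rotation, translation and uniform scaling.  Cohort separation
embeds each feature space into 2-D repeatedly (default 100 repeats,
t-SNE with random initialization per repeat; any `(X, seed) → n×2`
callable can be injected) and reports the full distribution of criteria
per group, not just means.

## The synthetic-data generator

The generator plants what the method assumes: sparse non-negative factor
triplets (default 120 genes × 80 samples × 5 layers at true rank 6,
50% sparse gene-factors — large enough for reliable recovery, small
enough for seconds-scale runs); data-type factors with one dominant
layer each, two of them spanning a second layer (cis-effects); four
contiguous tissue blocks of samples with elevated loadings on their
block's factors; optional per-layer scale imbalance reproducing the
variance-domination problem the weighting scheme addresses; additive
Gaussian noise (default SD 0.05) clipped at zero to keep the cube
non-negative (multiplicative noise behind a flag); drug responses linear
in the sample loadings with negative coefficients for sensitivity
factors plus one pure-noise null compound; and paired cohorts drawn from
the same block structure under frozen G and D, with an optional raw-
space batch shift.  Every generator is a pure function of its spec and
seed.

What this does *not* emulate: linkage and copy-number segment structure,
mutational signatures, realistic expression covariance, tissue-specific
standardization effects, or dose–response curve noise.  Passing tests
demonstrate the correctness and calibration of the machinery under the
model's own assumptions, not performance on real multi-omics panels.

## Problem sizes

The test and acceptance runs use cubes between 30×20×5 and 120×80×5 at
ranks 3–8, 500–1000 permutations for enrichment nulls, 10–20 simulation
seeds per property, and n up to 4000 for the nested-CV null calibration
— sizes chosen so the full suite completes in about a minute while every
statistical assertion retains adequate power.
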