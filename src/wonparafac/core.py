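"""Weighted orthogonal non-negative PARAFAC (WON-PARAFAC).

Fits a three-way non-negative CP/PARAFAC model to a genes x samples x
data-types cube by multiplicative alternating updates.  Three ingredients
distinguish the model from plain non-negative PARAFAC:

* a weight tensor, constant within each data-type slab, that rescales the
  squared-error loss so that low-variance data types (e.g. binary mutation
  calls) are not drowned out by high-variance ones (expression);
* an orthogonality penalty on the gene-factor matrix, derived from the
  natural gradient on the Stiefel manifold, that discourages a gene from
  loading on many factors and thereby favours factors capturing the same
  gene altered across data types (cis-effects);
* a mixing weight ``w`` in [0, 1] that blends the denominators of the
  unconstrained (w=0) and fully orthogonality-constrained (w=1)
  multiplicative updates for the gene mode.

The public entry point is :func:`fit`; the individual update steps are
exposed for testing and for the projection of new cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import khatri_rao as _scipy_khatri_rao

from .cube import DataCube, WeightTensor, compute_weights

MODE_GENE = "gene"
MODE_SAMPLE = "sample"
MODE_LAYER = "layer"
MODES = (MODE_GENE, MODE_SAMPLE, MODE_LAYER)

#: Floor applied to multiplicative-update denominators.
EPS = 1e-12


@dataclass
class FactorModel:
    """Non-negative factor triplet (G, C, D) with per-factor scales.

    G is genes x k (gene-factors), C is samples x k (cell/sample-factors),
    D is layers x k (data-type factors).  After :func:`normalize_and_sort`
    every factor column has unit l2 norm and ``scales[j]`` carries the
    product of the three norms removed from factor j, sorted descending.
    """

    G: np.ndarray
    C: np.ndarray
    D: np.ndarray
    k: int
    w: float = 0.1
    scales: np.ndarray | None = None
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    seed: int | None = None
    gene_ids: list | None = None
    sample_ids: list | None = None
    layer_names: list | None = None
    zero_factors: list = field(default_factory=list)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        for name, F in (("G", self.G), ("C", self.C), ("D", self.D)):
            if F.ndim != 2 or F.shape[1] != self.k:
                raise ValueError(f"{name} must be 2-D with {self.k} columns, got {F.shape}")
            if np.any(F < 0) or not np.all(np.isfinite(F)):
                raise ValueError(f"{name} must be non-negative and finite")

    def factor(self, mode: str) -> np.ndarray:
        return {MODE_GENE: self.G, MODE_SAMPLE: self.C, MODE_LAYER: self.D}[mode]

    def with_factor(self, mode: str, F: np.ndarray) -> "FactorModel":
        kw = {MODE_GENE: "G", MODE_SAMPLE: "C", MODE_LAYER: "D"}[mode]
        return replace(self, **{kw: F})

    def reconstruct(self) -> np.ndarray:
        """Dense reconstruction sum_j s_j g_j (x) c_j (x) d_j."""
        s = np.ones(self.k) if self.scales is None else self.scales
        return np.einsum("ir,jr,lr,r->ijl", self.G, self.C, self.D, s)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.G.shape[0], self.C.shape[0], self.D.shape[0])


def khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product; column j is kron(A[:, j], B[:, j]).

    Row ordering: A's index varies slowest, B's fastest — consistent with
    :func:`unfold` so that e.g. the gene-mode unfolding of the model equals
    ``khatri_rao(D, C) @ G.T``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"column-count mismatch: {A.shape[1]} vs {B.shape[1]}")
    return _scipy_khatri_rao(A, B)


def unfold(values: np.ndarray, mode: str) -> np.ndarray:
    """Matricize a (g, c, d) array along one mode.

    Gene mode  -> (c*d) x g, rows ordered layer-slow / sample-fast;
    sample mode -> (g*d) x c, rows layer-slow / gene-fast;
    layer mode -> (g*c) x d, rows sample-slow / gene-fast.
    """
    X = np.asarray(values)
    g, c, d = X.shape
    if mode == MODE_GENE:
        return X.transpose(2, 1, 0).reshape(d * c, g)
    if mode == MODE_SAMPLE:
        return X.transpose(2, 0, 1).reshape(d * g, c)
    if mode == MODE_LAYER:
        return X.transpose(1, 0, 2).reshape(c * g, d)
    raise ValueError(f"unknown mode {mode!r}")


def refold(mat: np.ndarray, mode: str, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`; round-trips exactly."""
    g, c, d = shape
    if mode == MODE_GENE:
        return mat.reshape(d, c, g).transpose(2, 1, 0)
    if mode == MODE_SAMPLE:
        return mat.reshape(d, g, c).transpose(1, 2, 0)
    if mode == MODE_LAYER:
        return mat.reshape(c, g, d).transpose(1, 0, 2)
    raise ValueError(f"unknown mode {mode!r}")


def paired_khatri_rao(model: FactorModel, mode: str) -> np.ndarray:
    """The Khatri-Rao product of the two factor matrices other than `mode`,
    ordered to match :func:`unfold`: Y_CD = kr(D, C), Y_GD = kr(D, G),
    Y_GC = kr(C, G)."""
    if mode == MODE_GENE:
        return khatri_rao(model.D, model.C)
    if mode == MODE_SAMPLE:
        return khatri_rao(model.D, model.G)
    if mode == MODE_LAYER:
        return khatri_rao(model.C, model.G)
    raise ValueError(f"unknown mode {mode!r}")


def _resolve_weights(cube: DataCube, weights) -> np.ndarray:
    if weights is None:
        return compute_weights(cube).values
    if isinstance(weights, WeightTensor):
        return weights.values
    if isinstance(weights, str) and weights == "uniform":
        return np.ones_like(cube.values)
    return np.asarray(weights, dtype=float)


def multiplicative_step(
    X_unf: np.ndarray,
    W_unf: np.ndarray,
    F: np.ndarray,
    Y: np.ndarray,
    w: float = 0.0,
    orthogonal_mode: bool = False,
) -> np.ndarray:
    """One multiplicative update of the factor matrix F for its mode.

    numerator  = (W (*) X)^T Y
    denominator = (W^T (*) (F Y^T)) Y                     (plain, w = 0)
                = (W^T (*) (F Y^T)) X F                   (orthogonal, w = 1)
    and for the gene mode the two denominators are mixed (1-w)/(w).
    Entries where numerator and denominator both vanish stay at zero.
    """
    num = (W_unf * X_unf).T @ Y
    recon_t = F @ Y.T  # dim_mode x (other dims), equals (Y F^T)^T
    WtR = W_unf.T * recon_t
    if orthogonal_mode and w > 0.0:
        den_orth = WtR @ X_unf @ F
        den = (1.0 - w) * (WtR @ Y) + w * den_orth if w < 1.0 else den_orth
    else:
        den = WtR @ Y
    new = F * num / np.maximum(den, EPS)
    # zero-locked entries (num ~ den ~ 0) remain exactly zero
    new[(num <= EPS) & (den <= EPS)] = 0.0
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("non-finite entries produced by multiplicative update")
    return new


def update_factor(cube: DataCube, weights, model: FactorModel, mode: str) -> FactorModel:
    """Replace one factor matrix by its multiplicative update.

    The orthogonality mix (model.w) applies to the gene mode only; sample
    and layer modes always use the plain weighted update.
    """
    Wv = _resolve_weights(cube, weights)
    X_unf = unfold(cube.values, mode)
    W_unf = unfold(Wv, mode)
    Y = paired_khatri_rao(model, mode)
    F = model.factor(mode)
    new = multiplicative_step(
        X_unf, W_unf, F, Y, w=model.w, orthogonal_mode=(mode == MODE_GENE)
    )
    return model.with_factor(mode, new)


def weighted_objective(cube: DataCube, weights, model: FactorModel) -> float:
    """Sum over cube entries of weight x squared residual."""
    Wv = _resolve_weights(cube, weights)
    resid = model.reconstruct() - cube.values
    return float(np.sum(Wv * resid * resid))


def _random_init(shape: tuple[int, int, int], k: int, rng: np.random.Generator,
                 target_norm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g, c, d = shape
    G = rng.uniform(size=(g, k))
    C = rng.uniform(size=(c, k))
    D = rng.uniform(size=(d, k))
    recon_norm = np.linalg.norm(np.einsum("ir,jr,lr->ijl", G, C, D))
    if recon_norm > 0 and target_norm > 0:
        s = (target_norm / recon_norm) ** (1.0 / 3.0)
        G, C, D = G * s, C * s, D * s
    return G, C, D


def fit(
    cube: DataCube,
    k: int,
    w: float = 0.1,
    weights=None,
    init="random",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> FactorModel:
    """Fit WON-PARAFAC by alternating gene -> sample -> layer updates.

    Parameters
    ----------
    cube : DataCube
        Non-negative genes x samples x layers array with identifier axes.
    k : int
        Number of factors (rank).
    w : float
        Orthogonality mixing weight in [0, 1]; 0 disables the constraint,
        1 uses the fully constrained gene update.  Default 0.1.
    weights : WeightTensor, "uniform", array or None
        Loss weights.  None computes the per-layer 1/||X_d||_F^2 scheme.
    init : "random", "eigen" or FactorModel
        "random" draws seeded uniform factors scaled to the cube norm;
        "eigen" uses absolute leading singular vectors of each unfolding.
    tol : float
        Relative objective-change stopping threshold.
    max_iter : int
        Maximum number of full update sweeps.
    seed : int, optional
        Seeds the random initialization (and eigen-init padding).

    Returns
    -------
    FactorModel, normalized and sorted, with the per-sweep objective trace.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if np.any(cube.values < 0):
        raise ValueError("cube must be non-negative")
    Wv = _resolve_weights(cube, weights)
    rng = np.random.default_rng(seed)
    if isinstance(init, FactorModel):
        G0 = init.G if init.scales is None else init.G * np.asarray(init.scales)
        model = replace(init, G=G0, w=w, k=k, scales=None,
                        objective_trace=[], converged=False)
    elif init == "random":
        G, C, D = _random_init(cube.shape, k, rng, float(np.linalg.norm(cube.values)))
        model = FactorModel(G=G, C=C, D=D, k=k, w=w, seed=seed)
    elif init == "eigen":
        from .selection import eigen_init

        model = eigen_init(cube, k, seed=seed)
        model = replace(model, w=w)
    else:
        raise ValueError(f"unknown init {init!r}")

    prev = weighted_objective(cube, Wv, model)
    trace = [prev]
    converged = False
    for _ in range(max_iter):
        for mode in MODES:
            model = update_factor(cube, Wv, model, mode)
        obj = weighted_objective(cube, Wv, model)
        if not np.isfinite(obj):
            raise FloatingPointError(f"objective diverged; trace={trace}")
        trace.append(obj)
        denom = max(prev, EPS)
        if abs(prev - obj) / denom < tol:
            converged = True
            break
        prev = obj

    model = replace(
        model,
        objective_trace=trace,
        converged=converged,
        seed=seed,
        gene_ids=cube.gene_ids,
        sample_ids=cube.sample_ids,
        layer_names=cube.layer_names,
    )
    return normalize_and_sort(model)


def normalize_and_sort(model: FactorModel) -> FactorModel:
    """Rescale factor columns to unit l2 norm and sort by scale.

    scales[j] is the product of the three removed norms; all-zero factors
    get scale 0, sort last, and are listed in ``zero_factors``.  The sort
    is stable (ties keep original factor order).  The reconstruction is
    unchanged.
    """
    G, C, D = model.G.copy(), model.C.copy(), model.D.copy()
    prior = np.ones(model.k) if model.scales is None else np.asarray(model.scales, float)
    norms = np.stack([np.linalg.norm(F, axis=0) for F in (G, C, D)])
    scales = prior * norms.prod(axis=0)
    for F, nrm in zip((G, C, D), norms):
        nz = nrm > 0
        F[:, nz] /= nrm[nz]
    order = np.argsort(-scales, kind="stable")
    zero = [int(j) for j in np.where(scales[order] == 0)[0]]
    return replace(
        model,
        G=G[:, order],
        C=C[:, order],
        D=D[:, order],
        scales=scales[order],
        zero_factors=zero,
    )


def explained_variation(cube: DataCube, model: FactorModel, by: str = "total"):
    """1 - ||residual||^2 / ||data||^2, overall or per sample / per layer.

    Per-sample values use that sample's genes x layers slice; zero-norm
    units are reported as NaN.
    """
    X = cube.values
    R = model.reconstruct() - X
    if by == "total":
        tot = float(np.sum(X * X))
        return 1.0 - float(np.sum(R * R)) / tot if tot > 0 else np.nan
    if by == "sample":
        axis = (0, 2)
    elif by == "layer":
        axis = (0, 1)
    else:
        raise ValueError(f"unknown 'by' {by!r}")
    tot = np.sum(X * X, axis=axis)
    res = np.sum(R * R, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        ev = 1.0 - res / tot
    ev[tot == 0] = np.nan
    return ev


def greedy_cosine_match(true_factors: np.ndarray, fitted_factors: np.ndarray) -> np.ndarray:
    """Greedy best-cosine matching of true factor columns to fitted ones.

    Repeatedly pairs the remaining (true, fitted) columns with the highest
    cosine similarity; returns the matched cosine per true column.  Used to
    score planted-factor recovery, where factor order and scale are
    arbitrary.
    """
    A = np.asarray(true_factors, dtype=float)
    B = np.asarray(fitted_factors, dtype=float)
    An = A / np.maximum(np.linalg.norm(A, axis=0), EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), EPS)
    S = An.T @ Bn
    out = np.full(A.shape[1], np.nan)
    for _ in range(min(A.shape[1], B.shape[1])):
        i, j = np.unravel_index(np.argmax(S), S.shape)
        out[i] = S[i, j]
        S[i, :] = -np.inf
        S[:, j] = -np.inf
    return out


def dt_similarity(model: FactorModel) -> np.ndarray:
    """Cosine similarity between data-type factor rows (layers x layers).

    Pairs involving an all-zero row are NaN.
    """
    D = model.D
    nrm = np.linalg.norm(D, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = (D @ D.T) / np.outer(nrm, nrm)
    S[nrm == 0, :] = np.nan
    S[:, nrm == 0] = np.nan
    d = model.D.shape[0]
    S[np.arange(d), np.arange(d)] = np.where(nrm > 0, 1.0, np.nan)
    return S
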