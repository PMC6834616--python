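"""Choosing the number of factors.

Each candidate rank is fitted from a deterministic eigen-style
initialization and scored by (a) a Gaussian-profile AIC,
AIC = n ln(RSS/n) + 2p with p = k (g + c + d), and (b) the average cosine
similarity between factor pairs measured on the Khatri-Rao product of the
gene and data-type factor matrices (Y_GD), a redundancy measure.  A good
rank has low AIC and low redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import svds

from . import core
from .core import MODES, DataCube, FactorModel, khatri_rao, unfold


@dataclass
class RankScanResult:
    ks: list[int]
    objective: list[float]
    aic: list[float]
    mean_cosine: list[float]
    chosen_k: int
    failures: dict | None = None


def _leading_abs_singular(mat: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """|leading k right-singular vectors| of mat (rows x dim), padded with
    seeded uniform columns when the mode dimension limits the rank."""
    dim = mat.shape[1]
    k_avail = min(k, min(mat.shape))
    if k_avail < min(mat.shape) - 1 and min(mat.shape) > 60:
        _, _, vt = svds(mat, k=k_avail)
        V = vt[::-1].T  # svds returns ascending singular values
    else:
        _, _, vt = np.linalg.svd(mat, full_matrices=False)
        V = vt[:k_avail].T
    F = np.abs(V)
    if k_avail < k:
        scale = max(float(F.mean()), 1e-3)
        pad = rng.uniform(0.0, 2.0 * scale, size=(dim, k - k_avail))
        F = np.hstack([F, pad])
    return F


def eigen_init(cube: DataCube, k: int, seed: int | None = None) -> FactorModel:
    """Deterministic initial factors from each unfolding's singular vectors.

    The absolute value resolves the sign ambiguity and guarantees
    non-negativity; for the layer mode (usually d < k) the missing columns
    are seeded uniform.  Factors are rescaled so the initial reconstruction
    matches the cube's Frobenius norm.
    """
    rng = np.random.default_rng(seed)
    mats = {m: unfold(cube.values, m) for m in MODES}
    G = _leading_abs_singular(mats["gene"], k, rng)
    C = _leading_abs_singular(mats["sample"], k, rng)
    D = _leading_abs_singular(mats["layer"], k, rng)
    recon = np.einsum("ir,jr,lr->ijl", G, C, D)
    rn, xn = np.linalg.norm(recon), np.linalg.norm(cube.values)
    if rn > 0 and xn > 0:
        s = (xn / rn) ** (1.0 / 3.0)
        G, C, D = G * s, C * s, D * s
    return FactorModel(G=G, C=C, D=D, k=k, seed=seed,
                       gene_ids=cube.gene_ids, sample_ids=cube.sample_ids,
                       layer_names=cube.layer_names)


def aic(model: FactorModel, cube: DataCube) -> float:
    """Gaussian-profile AIC: n ln(RSS/n) + 2 k (g + c + d).

    RSS is the unweighted squared residual over all n cube entries.
    A perfect fit (RSS = 0) returns -inf, flagging overfit.
    """
    resid = model.reconstruct() - cube.values
    rss = float(np.sum(resid * resid))
    n = cube.values.size
    g, c, d = cube.shape
    p = model.k * (g + c + d)
    if rss <= 0:
        return float("-inf")
    return n * np.log(rss / n) + 2 * p


def mean_factor_cosine(model: FactorModel) -> float:
    """Mean pairwise cosine similarity of Y_GD = kr(D, G) columns.

    Non-negative factors make every pair similarity >= 0; zero columns
    are skipped.  Requires k >= 2.
    """
    if model.k < 2:
        raise ValueError("mean_factor_cosine requires k >= 2")
    Y = khatri_rao(model.D, model.G)
    nrm = np.linalg.norm(Y, axis=0)
    keep = nrm > 0
    Yn = Y[:, keep] / nrm[keep]
    m = Yn.shape[1]
    if m < 2:
        return float("nan")
    S = Yn.T @ Yn
    iu = np.triu_indices(m, k=1)
    return float(S[iu].mean())


def scan_ranks(
    cube: DataCube,
    ks=tuple(range(10, 201, 10)),
    w: float = 0.1,
    seed: int | None = None,
    weights=None,
    tol: float = 1e-6,
    max_iter: int = 500,
    aic_band: float = 0.01,
    cosine_threshold: float = 0.5,
) -> RankScanResult:
    """Fit every rank in ``ks`` from eigen init and pick one.

    chosen_k is the smallest rank whose AIC lies within ``aic_band`` of
    the scan's minimum (band measured relative to the AIC spread) and
    whose mean factor cosine stays below ``cosine_threshold``; if no rank
    passes the cosine guard the plain AIC minimizer is returned.  Failed
    fits are recorded and skipped.
    """
    ks = [int(k) for k in ks]
    rows = {"k": [], "objective": [], "aic": [], "mean_cosine": []}
    failures: dict[int, str] = {}
    for k in ks:
        try:
            model = core.fit(cube, k=k, w=w, weights=weights, init="eigen",
                             tol=tol, max_iter=max_iter, seed=seed)
            rows["k"].append(k)
            rows["objective"].append(model.objective_trace[-1])
            rows["aic"].append(aic(model, cube))
            rows["mean_cosine"].append(
                mean_factor_cosine(model) if k >= 2 else 0.0)
        except Exception as exc:  # a failed fit must not kill the scan
            failures[k] = str(exc)
    if not rows["k"]:
        raise RuntimeError(f"every fit in the scan failed: {failures}")
    a = np.asarray(rows["aic"], dtype=float)
    cos = np.asarray(rows["mean_cosine"], dtype=float)
    spread = float(a.max() - a.min())
    band = a.min() + aic_band * spread
    if not np.isfinite(band):  # e.g. a perfect fit scored -inf
        band = a.min()
    ok = (a <= band) & (cos < cosine_threshold)
    if ok.any():
        chosen = rows["k"][int(np.argmax(ok))]  # smallest k in the band
    else:
        chosen = rows["k"][int(np.argmin(a))]
    return RankScanResult(ks=rows["k"], objective=rows["objective"],
                          aic=rows["aic"], mean_cosine=rows["mean_cosine"],
                          chosen_k=chosen, failures=failures or None)
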