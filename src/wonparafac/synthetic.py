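"""Seeded synthetic datasets with the structure the factorization assumes.

The generators plant sparse non-negative factor triplets, per-layer scale
imbalance between data types, cis-effect factors active in several layers,
tissue blocks of samples with elevated loadings, drug responses linear in
the sample factors, and paired cohorts sharing the gene/data-type factors —
so every stage of the pipeline has a positive and a null control without
any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FactorModel
from .cube import DataCube

DEFAULT_LAYER_NAMES = ["GE(+)", "GE(-)", "CN(+)", "CN(-)", "MT"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-factor generator.

    Defaults describe a toy cube large enough for reliable factor
    recovery yet small enough for seconds-scale fits: 120 genes x 80
    samples x 5 data-type layers at true rank 6, half-sparse factors,
    moderate additive noise, two cis-effect factors and four tissue
    blocks of equal size.
    """

    g: int = 120
    c: int = 80
    d: int = 5
    k_true: int = 6
    sparsity: float = 0.5
    layer_scales: tuple | None = None
    noise_sd: float = 0.05
    noise_kind: str = "additive"  # or "multiplicative"
    cis_factors: int = 2
    tissue_blocks: int = 4
    block_boost: float = 2.0
    beta: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k_true > min(self.g, self.c):
            raise ValueError("k_true must not exceed min(g, c)")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.layer_scales is not None:
            ls = np.asarray(self.layer_scales, float)
            if ls.shape != (self.d,) or np.any(ls <= 0):
                raise ValueError("layer_scales must be d positive values")


def _sparse_nonneg(rng: np.random.Generator, rows: int, k: int, sparsity: float) -> np.ndarray:
    F = rng.uniform(0.2, 1.0, size=(rows, k))
    mask = rng.uniform(size=(rows, k)) < sparsity
    F[mask] = 0.0
    for j in range(k):  # a factor must touch at least one row
        if not F[:, j].any():
            F[rng.integers(rows), j] = rng.uniform(0.2, 1.0)
    return F


def _layer_names(d: int) -> list[str]:
    if d == len(DEFAULT_LAYER_NAMES):
        return list(DEFAULT_LAYER_NAMES)
    return [f"L{i}" for i in range(d)]


def planted_factors(spec: SyntheticSpec, rng: np.random.Generator) -> FactorModel:
    """Draw the ground-truth factor triplet for a spec."""
    G = _sparse_nonneg(rng, spec.g, spec.k_true, spec.sparsity)
    C = _sparse_nonneg(rng, spec.c, spec.k_true, spec.sparsity * 0.5)

    # tissue blocks: factor j (cyclically) boosts one contiguous sample block
    blocks = np.array_split(np.arange(spec.c), spec.tissue_blocks)
    for j in range(spec.k_true):
        b = blocks[j % spec.tissue_blocks]
        C[b, j] += spec.block_boost * rng.uniform(0.5, 1.0, size=b.size)

    # data-type factors: one dominant layer each; cis factors span >= 2 layers
    D = np.zeros((spec.d, spec.k_true))
    for j in range(spec.k_true):
        lead = j % spec.d
        D[lead, j] = rng.uniform(0.7, 1.0)
        if j < spec.cis_factors:
            other = (lead + 1) % spec.d
            D[other, j] = rng.uniform(0.5, 1.0)
    for l in np.flatnonzero(D.sum(axis=1) == 0):  # no all-zero layer slabs
        D[l, rng.integers(spec.k_true)] = rng.uniform(0.3, 0.6)
    return FactorModel(G=G, C=C, D=D, k=spec.k_true, w=0.0, seed=spec.seed)


def make_planted_cube(spec: SyntheticSpec) -> tuple[DataCube, FactorModel]:
    """Planted-rank cube = per-layer-scaled reconstruction plus clipped noise."""
    rng = np.random.default_rng(spec.seed)
    truth = planted_factors(spec, rng)
    X = truth.reconstruct()
    if spec.layer_scales is not None:
        X = X * np.asarray(spec.layer_scales, float)[None, None, :]
    if spec.noise_sd > 0:
        if spec.noise_kind == "additive":
            X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
        elif spec.noise_kind == "multiplicative":
            X = X * np.exp(rng.normal(0.0, spec.noise_sd, size=X.shape))
        else:
            raise ValueError(f"unknown noise_kind {spec.noise_kind!r}")
    X = np.maximum(X, 0.0)
    cube = DataCube(
        values=X,
        gene_ids=[f"gene{i:04d}" for i in range(spec.g)],
        sample_ids=[f"s{i:04d}" for i in range(spec.c)],
        layer_names=_layer_names(spec.d),
    )
    return cube, truth


def make_annotations(
    spec: SyntheticSpec,
    truth: FactorModel | None = None,
    n_decoy_sets: int = 10,
    set_size: int = 15,
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Tissue labels matching the planted blocks, plus gene sets.

    One signal set per true factor (its top-loading genes) and
    ``n_decoy_sets`` random decoys of the same size; CSEA/GSEA positive
    and null controls follow.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if truth is None:
        truth = planted_factors(spec, np.random.default_rng(spec.seed))
    samples = [f"s{i:04d}" for i in range(spec.c)]
    genes = [f"gene{i:04d}" for i in range(spec.g)]
    blocks = np.array_split(np.arange(spec.c), spec.tissue_blocks)
    tissue = pd.Series(index=samples, dtype=object, name="tissue_type")
    for b, idx in enumerate(blocks):
        tissue.iloc[idx] = f"tissue{b}"

    sets: dict[str, list[str]] = {}
    for j in range(spec.k_true):
        top = np.argsort(-truth.G[:, j])[:set_size]
        sets[f"factor{j}_top_genes"] = [genes[i] for i in top]
    for m in range(n_decoy_sets):
        pick = rng.choice(spec.g, size=set_size, replace=False)
        sets[f"decoy{m}"] = [genes[i] for i in pick]
    return tissue, sets


def make_response(
    spec: SyntheticSpec,
    C_true: np.ndarray,
    noise_sd: float = 0.1,
    intercept: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """AUC-like responses linear in the sample factors plus noise.

    Negative coefficients mark sensitivity factors (lower AUC = more
    sensitive).  Without an explicit ``spec.beta``, three compounds are
    generated: one with mixed-sign sparse effects, one sensitivity-only,
    one pure noise (null control).
    """
    rng = np.random.default_rng(spec.seed + 2)
    k = C_true.shape[1]
    betas = spec.beta
    if betas is None:
        b0 = np.zeros(k)
        b0[0], b0[1 % k] = -2.0, 1.0
        b1 = np.zeros(k)
        b1[2 % k] = -1.5
        betas = {"drug_mixed": b0, "drug_sens": b1, "drug_null": np.zeros(k)}
    samples = [f"s{i:04d}" for i in range(C_true.shape[0])]
    out = {}
    for name, b in betas.items():
        b = np.asarray(b, float)
        out[name] = intercept + C_true @ b + rng.normal(0.0, noise_sd, size=C_true.shape[0])
    return pd.DataFrame(out, index=samples), {k_: np.asarray(v, float) for k_, v in betas.items()}


def make_paired_cohort(
    spec: SyntheticSpec,
    model: FactorModel,
    shift: float = 0.0,
    n_samples: int | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> tuple[DataCube, np.ndarray]:
    """A second cohort sharing the model's gene/data-type factors.

    New sample loadings are drawn with the same block structure; the cube
    is rebuilt from the frozen G and D plus cohort noise.  ``shift`` adds a
    constant raw-space offset (a batch effect) that separates the cohorts
    in raw feature space but not in factor space.
    """
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    n = spec.c if n_samples is None else n_samples
    k = model.k
    P = _sparse_nonneg(rng, n, k, spec.sparsity * 0.5)
    blocks = np.array_split(np.arange(n), spec.tissue_blocks)
    for j in range(k):
        b = blocks[j % spec.tissue_blocks]
        P[b, j] += spec.block_boost * rng.uniform(0.5, 1.0, size=b.size)
    s = np.ones(k) if model.scales is None else np.asarray(model.scales)
    X = np.einsum("ir,jr,lr,r->ijl", model.G, P, model.D, s)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        X = X + rng.normal(0.0, sd, size=X.shape)
    X = np.maximum(X + shift, 0.0)
    cube = DataCube(
        values=X,
        gene_ids=(model.gene_ids or [f"gene{i:04d}" for i in range(model.G.shape[0])]),
        sample_ids=[f"p{i:04d}" for i in range(n)],
        layer_names=(model.layer_names or _layer_names(model.D.shape[0])),
    )
    return cube, P
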