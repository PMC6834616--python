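"""Projecting an independent cohort onto fixed gene/data-type factors.

A model fitted on one system (e.g. cell lines) is transferred to a second
cohort (e.g. patient-derived xenografts) by freezing the gene-factor and
data-type-factor matrices and optimizing only the new sample-factor matrix
P under min_{P>=0} ||Y_GD P^T - X_(P)||_F^2, using the same multiplicative
update as the sample mode of the joint fit.  Downstream utilities score
the projection against a permuted-cube baseline, attribute each projected
sample to tissue-associated factors, translate per-compound drug models,
and quantify cohort separation in 2-D embeddings with the Fisher
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (EPS, MODE_SAMPLE, DataCube, FactorModel, khatri_rao,
                   multiplicative_step, unfold)
from .drugs import DrugModel


@dataclass
class ProjectionResult:
    P: np.ndarray  # new-cohort samples x k, non-negative
    explained_variation: np.ndarray  # per sample
    objective_trace: list
    converged: bool
    sample_ids: list | None = None
    seed: int | None = None
    baseline_explained_variation: np.ndarray | None = None

    @property
    def total_explained_variation(self) -> float:
        return float(np.nanmean(self.explained_variation))


def _scaled_ygd(model: FactorModel) -> np.ndarray:
    Y = khatri_rao(model.D, model.G)
    if model.scales is not None:
        Y = Y * np.asarray(model.scales)[None, :]
    return Y


def _check_axes(new_cube: DataCube, model: FactorModel) -> None:
    if model.gene_ids is not None and list(new_cube.gene_ids) != list(model.gene_ids):
        raise ValueError("gene axis mismatch between cohort cube and model")
    if model.layer_names is not None and list(new_cube.layer_names) != list(model.layer_names):
        raise ValueError("layer axis mismatch between cohort cube and model")
    if (new_cube.shape[0], new_cube.shape[2]) != (model.G.shape[0], model.D.shape[0]):
        raise ValueError("cohort cube dimensions do not match the model")


def project(
    new_cube: DataCube,
    model: FactorModel,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> ProjectionResult:
    """Non-negative projection of a cohort onto frozen G and D.

    P is seeded uniform (scaled to the cohort norm) and iterated with the
    sample-mode multiplicative update under uniform weights until the
    relative objective change drops below ``tol``.  Per-sample explained
    variation is 1 - ||residual fiber||^2 / ||data fiber||^2.
    """
    _check_axes(new_cube, model)
    Y = _scaled_ygd(model)  # (d*g) x k
    Xc = unfold(new_cube.values, MODE_SAMPLE)  # (d*g) x c_new
    n_new = Xc.shape[1]
    k = model.k
    rng = np.random.default_rng(seed)
    P = rng.uniform(size=(n_new, k))
    yn, xn = np.linalg.norm(Y @ P.T), np.linalg.norm(Xc)
    if yn > 0 and xn > 0:
        P *= xn / yn
    W1 = np.ones_like(Xc)
    prev = float(np.sum((Y @ P.T - Xc) ** 2))
    trace = [prev]
    converged = False
    for _ in range(max_iter):
        P = multiplicative_step(Xc, W1, P, Y, w=0.0, orthogonal_mode=False)
        obj = float(np.sum((Y @ P.T - Xc) ** 2))
        trace.append(obj)
        if abs(prev - obj) / max(prev, EPS) < tol:
            converged = True
            break
        prev = obj
    resid = Y @ P.T - Xc
    tot = np.sum(Xc * Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ev = 1.0 - np.sum(resid * resid, axis=0) / tot
    ev[tot == 0] = np.nan
    return ProjectionResult(P=P, explained_variation=ev, objective_trace=trace,
                            converged=converged, sample_ids=new_cube.sample_ids,
                            seed=seed)


def permuted_baseline(
    new_cube: DataCube,
    model: FactorModel,
    n_perm: int = 1,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Explained variation of projections of permuted cubes.

    Gene and sample indices are permuted independently within each layer,
    destroying both cross-layer and factor structure while preserving
    every layer's value distribution.  Returns an (n_perm, samples) array.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, new_cube.shape[1]))
    for b in range(n_perm):
        V = new_cube.values.copy()
        for l in range(V.shape[2]):
            V[:, :, l] = V[rng.permutation(V.shape[0]), :, l]
            V[:, :, l] = V[:, rng.permutation(V.shape[1]), l]
        perm_cube = DataCube(values=V, gene_ids=new_cube.gene_ids,
                             sample_ids=new_cube.sample_ids,
                             layer_names=new_cube.layer_names)
        res = project(perm_cube, model, tol=tol, max_iter=max_iter,
                      seed=rng.integers(2**31))
        out[b] = res.explained_variation
    return out


def tissue_association(P: np.ndarray, factor_sets: dict[str, list[int]]) -> pd.DataFrame:
    """Share of each sample's loading mass on tissue-associated factors.

    For sample i and tissue factor set T: sum_{k in T} P[i,k] / sum_l P[i,l];
    close to 1 when the sample's variation is captured by T.  Zero-loading
    rows are NaN.
    """
    P = np.asarray(P, dtype=float)
    tot = P.sum(axis=1)
    cols = {}
    for tissue, idx in factor_sets.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[tissue] = np.where(tot > 0, P[:, list(idx)].sum(axis=1) / tot, np.nan)
    return pd.DataFrame(cols)


def fisher_criterion(points: np.ndarray, labels: np.ndarray) -> float:
    """Separation of two groups: |m1 - m2|^2 / (s1^2 + s2^2).

    Means are group centroids; each group's variance is the trace of its
    covariance (population convention), making the measure invariant to
    rotation, translation and uniform scaling of the coordinates.
    Identical means give 0; two point masses at distinct locations give
    +inf.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    A, B = (X[labels == grp] for grp in groups)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    m1, m2 = A.mean(axis=0), B.mean(axis=0)
    num = float(np.sum((m1 - m2) ** 2))
    s1 = float(np.sum(A.var(axis=0, ddof=0)))
    s2 = float(np.sum(B.var(axis=0, ddof=0)))
    if s1 + s2 == 0:
        return float("inf") if num > 0 else 0.0
    return num / (s1 + s2)


def _tsne_embed(X: np.ndarray, seed: int, perplexity: float = 30.0) -> np.ndarray:
    from sklearn.manifold import TSNE

    perp = min(perplexity, (X.shape[0] - 1) / 3.0)
    return TSNE(n_components=2, init="random", random_state=seed,
                perplexity=perp).fit_transform(X)


def embedding_separation(
    features_by_space: dict[str, np.ndarray],
    cohort_labels: np.ndarray,
    groups: np.ndarray,
    n_repeats: int = 100,
    seed: int | None = None,
    embedding="tsne",
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """Fisher criterion between cohorts per group over repeated embeddings.

    Every repeat re-embeds each feature space into 2-D with a fresh seed
    (stochastic embeddings such as t-SNE give a distribution of criteria,
    reported in full), then scores cohort separation within each group
    (e.g. each cancer type).  ``embedding`` is either "tsne" or a callable
    (X, seed) -> n x 2 array.  Groups present in only one cohort are
    skipped with a reason recorded in ``df.attrs['skipped']``.
    """
    cohort_labels = np.asarray(cohort_labels)
    groups = np.asarray(groups)
    if embedding == "tsne":
        embed = lambda X, s: _tsne_embed(X, s, perplexity)  # noqa: E731
    elif callable(embedding):
        embed = embedding
    else:
        raise ValueError("embedding must be 'tsne' or a callable")
    base = np.random.default_rng(seed).integers(0, 2**31 - 1)
    rows, skipped = [], {}
    uniq_groups = pd.unique(groups)
    for rep in range(n_repeats):
        for space, X in features_by_space.items():
            pts = embed(np.asarray(X, dtype=float), int((base + rep) % (2**31 - 1)))
            for grp in uniq_groups:
                m = groups == grp
                cohorts = pd.unique(cohort_labels[m])
                if len(cohorts) != 2:
                    skipped[str(grp)] = "group present in fewer than two cohorts"
                    continue
                f = fisher_criterion(pts[m], cohort_labels[m])
                rows.append({"repeat": rep, "group": grp, "space": space,
                             "fisher": f})
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


def translate_predictions(
    drug_models: dict[str, DrugModel],
    P: np.ndarray | pd.DataFrame,
    response_map: list[tuple[str, str]],
    cohort_response: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate model-predicted AUC with a cohort's observed responses.

    ``response_map`` pairs each trained compound with a cohort treatment
    column (drug-class matching is configuration, not code).  Returns one
    row per mapped pair: (compound, treatment, r, p, fdr, n); unmapped or
    unknown names are skipped with a reason.
    """
    if isinstance(P, pd.DataFrame):
        sample_ids = list(P.index)
        P_arr = P.to_numpy(dtype=float)
    else:
        P_arr = np.asarray(P, dtype=float)
        sample_ids = list(cohort_response.index)[: P_arr.shape[0]]
    rows, skipped = [], {}
    for compound, treatment in response_map:
        if compound not in drug_models:
            skipped[(compound, treatment)] = "no trained model for compound"
            continue
        if treatment not in cohort_response.columns:
            skipped[(compound, treatment)] = "treatment absent from cohort response"
            continue
        pred = drug_models[compound].predict(P_arr)
        obs = cohort_response[treatment].reindex(sample_ids).to_numpy(dtype=float)
        ok = np.isfinite(obs)
        if ok.sum() < 3:
            skipped[(compound, treatment)] = "fewer than 3 observed responses"
            continue
        r, p = stats.pearsonr(pred[ok], obs[ok])
        rows.append({"compound": compound, "treatment": treatment,
                     "r": float(r), "p": float(p), "n": int(ok.sum())})
    df = pd.DataFrame(rows, columns=["compound", "treatment", "r", "p", "n"])
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr"] = pd.Series(dtype=float)
    df.attrs["skipped"] = skipped
    return df
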