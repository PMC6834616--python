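"""Factor enrichment: cell-set (CSEA) and gene-set (GSEA) analysis.

CSEA asks whether a sample category (e.g. a tissue type) concentrates on
samples with high loadings on a factor.  For a category T of size n_T the
score is

    ES = sqrt(n_T) * mean_{i in T}(c_i - m) / sigma

with m and sigma the mean and (population) standard deviation of all
loadings; under random category membership ES is approximately standard
normal, so a right-tailed normal test gives p-values, followed by
Benjamini-Hochberg FDR across categories.

GSEA links factors to gene sets in two steps: each gene's expression is
regressed on all factor loadings jointly, and each factor's column of
coefficients ranks the genes for a weighted Kolmogorov-Smirnov running-sum
enrichment score (weight exponent 1, as in the original GSEA).  The null
distribution comes from permuting the samples of the expression matrix and
re-running the regression; FDR is computed from the pooled normalized null,
positive and negative sides separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.2


def _as_loading_series(loadings, sample_ids=None) -> pd.Series:
    if isinstance(loadings, pd.Series):
        return loadings.astype(float)
    arr = np.asarray(loadings, dtype=float)
    idx = list(sample_ids) if sample_ids is not None else list(range(arr.size))
    return pd.Series(arr, index=idx)


def csea_score(loadings: np.ndarray, member_mask: np.ndarray,
               total_n: bool = False) -> float:
    """Enrichment score of one category against one factor's loadings.

    ``total_n=False`` (default) uses n = category size, the reading under
    which ES ~ N(0, 1) for random membership; ``total_n=True`` applies the
    literal formula with n = number of samples.
    """
    c = np.asarray(loadings, dtype=float)
    m = c.mean()
    sigma = c.std(ddof=0)
    if sigma <= 0:
        raise ValueError("degenerate factor: zero loading variance")
    sub = c[member_mask]
    if sub.size == 0:
        raise ValueError("empty category")
    n = c.size if total_n else sub.size
    return float(np.sqrt(n) * np.sum(sub - m) / (n * sigma))


def csea(
    factor_loadings,
    annotation: pd.Series,
    sample_ids=None,
    fdr_threshold: float = FDR_THRESHOLD,
    total_n: bool = False,
) -> pd.DataFrame:
    """Associate one factor's sample loadings with sample categories.

    Returns one row per category: (category, n, es, p, fdr, significant),
    FDR by Benjamini-Hochberg across the categories of this factor.
    Samples missing from either input are dropped and counted.
    """
    load = _as_loading_series(factor_loadings, sample_ids)
    ann = annotation.dropna()
    shared = load.index.intersection(ann.index)
    if len(shared) < len(load) or len(shared) < len(ann):
        pass  # dropped samples are implied by the n column
    load = load.loc[shared]
    ann = ann.loc[shared]
    cats = ann.unique()
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    rows = []
    for cat in cats:
        mask = (ann == cat).to_numpy()
        es = csea_score(load.to_numpy(), mask, total_n=total_n)
        p = float(stats.norm.sf(es))  # right tail
        rows.append({"category": cat, "n": int(mask.sum()), "es": es, "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_threshold
    return df.sort_values("p", ignore_index=True)


def csea_all_factors(C, annotation: pd.Series, sample_ids=None,
                     fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """CSEA for every column of a sample-factor matrix; adds a 'factor' column."""
    C = np.asarray(C, dtype=float)
    out = []
    for j in range(C.shape[1]):
        t = csea(C[:, j], annotation, sample_ids=sample_ids,
                 fdr_threshold=fdr_threshold)
        t.insert(0, "factor", j)
        out.append(t)
    return pd.concat(out, ignore_index=True)


def regress_expression_on_factors(
    expression: np.ndarray | pd.DataFrame,
    C: np.ndarray,
    joint: bool = True,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Per-gene linear regression of expression on the factor loadings.

    Each gene's expression across samples is regressed (with intercept) on
    all k loadings jointly; the genes x k slope matrix is returned.  A
    rank-deficient design falls back to a tiny ridge penalty.  With
    ``joint=False`` each factor is regressed separately (univariate
    slopes).
    """
    E = expression.to_numpy(dtype=float) if isinstance(expression, pd.DataFrame) \
        else np.asarray(expression, dtype=float)
    C = np.asarray(C, dtype=float)
    n, k = C.shape
    if E.shape[1] != n:
        raise ValueError("expression samples do not match factor rows")
    if joint and k >= n:
        raise ValueError("joint regression needs k < number of samples")
    if not joint:
        Cc = C - C.mean(axis=0)
        Ec = E - E.mean(axis=1, keepdims=True)
        denom = np.sum(Cc * Cc, axis=0)
        denom = np.where(denom > 0, denom, np.inf)
        return (Ec @ Cc) / denom
    X = np.column_stack([np.ones(n), C])
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        XtX = XtX + ridge * np.eye(XtX.shape[0])
    coef = np.linalg.solve(XtX, X.T @ E.T)  # (k+1) x genes
    return coef[1:].T


def enrichment_score(ranked_values: np.ndarray, in_set: np.ndarray,
                     exponent: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score on a pre-ranked list.

    ``ranked_values`` must already be sorted in the ranking order
    (descending coefficient); ``in_set`` marks member positions.  Hit
    steps are |value|^exponent normalized to the set total, miss steps
    1/(N - N_hit); the ES is the signed maximum deviation from zero.
    """
    r = np.abs(np.asarray(ranked_values, dtype=float)) ** exponent
    hit = np.asarray(in_set, dtype=bool)
    n = r.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must be a proper nonempty subset of the universe")
    hit_w = np.where(hit, r, 0.0)
    tot = hit_w.sum()
    if tot <= 0:  # all member coefficients exactly zero: flat hit steps
        hit_w = hit.astype(float)
        tot = float(n_hit)
    steps = hit_w / tot - (~hit).astype(float) / (n - n_hit)
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def _scores_for_coefficients(coefs: np.ndarray, set_masks: np.ndarray,
                             exponent: float) -> np.ndarray:
    order = np.argsort(-coefs, kind="stable")
    ranked = coefs[order]
    return np.array([
        enrichment_score(ranked, mask[order], exponent=exponent)
        for mask in set_masks
    ])


def gsea(
    expression: np.ndarray | pd.DataFrame,
    C: np.ndarray,
    factor: int,
    gene_sets: dict[str, list],
    gene_ids: list | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
    exponent: float = 1.0,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Permutation GSEA for one factor's expression-regression coefficients.

    The observed ranking comes from :func:`regress_expression_on_factors`;
    every permutation shuffles the expression matrix's sample axis and
    re-runs the regression before scoring, so the null respects the
    gene-gene correlation structure.  Normalized scores (ES divided by the
    same-sign null mean per set) are pooled across sets for the FDR.

    Returns (set, size, es, nes, p, fdr, significant, direction); sets
    smaller than ``min_size`` after intersection are skipped.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(expression, pd.DataFrame):
        gene_ids = list(expression.index)
        E = expression.to_numpy(dtype=float)
    else:
        E = np.asarray(expression, dtype=float)
        if gene_ids is None:
            gene_ids = list(range(E.shape[0]))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    names, masks, skipped = [], [], {}
    for name, members in gene_sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < min_size:
            skipped[name] = f"only {len(idx)} genes in universe (min {min_size})"
            continue
        mask = np.zeros(len(gene_ids), dtype=bool)
        mask[idx] = True
        names.append(name)
        masks.append(mask)
    if not names:
        raise ValueError(f"no usable gene sets: {skipped}")
    masks = np.asarray(masks)

    coefs = regress_expression_on_factors(E, C)[:, factor]
    obs = _scores_for_coefficients(coefs, masks, exponent)

    rng = np.random.default_rng(seed)
    n_samples = E.shape[1]
    null = np.empty((n_perm, len(names)))
    for b in range(n_perm):
        perm = rng.permutation(n_samples)
        coefs_b = regress_expression_on_factors(E[:, perm], C)[:, factor]
        null[b] = _scores_for_coefficients(coefs_b, masks, exponent)

    nes_obs, nes_null = _normalize_scores(obs, null)
    p = np.array([
        _empirical_p(obs[i], null[:, i]) for i in range(len(names))
    ])
    fdr = _pooled_fdr(nes_obs, nes_null)
    df = pd.DataFrame({
        "set": names,
        "size": masks.sum(axis=1),
        "es": obs,
        "nes": nes_obs,
        "p": p,
        "fdr": fdr,
    })
    df["significant"] = df["fdr"] < fdr_threshold
    df["direction"] = np.where(df["es"] >= 0, "positive", "negative")
    df.attrs["skipped"] = skipped
    return df.sort_values("fdr", ignore_index=True)


def _empirical_p(es: float, null_es: np.ndarray) -> float:
    """Same-sign tail probability with the +1 permutation correction."""
    if es >= 0:
        pos = null_es[null_es >= 0]
        return (1.0 + np.sum(pos >= es)) / (1.0 + pos.size) if pos.size else 1.0
    neg = null_es[null_es < 0]
    return (1.0 + np.sum(neg <= es)) / (1.0 + neg.size) if neg.size else 1.0


def _normalize_scores(obs: np.ndarray, null: np.ndarray):
    """Divide scores by the per-set same-sign null mean magnitude."""
    n_sets = obs.size
    pos_mean = np.array([
        null[null[:, i] > 0, i].mean() if np.any(null[:, i] > 0) else np.nan
        for i in range(n_sets)
    ])
    neg_mean = np.array([
        -null[null[:, i] < 0, i].mean() if np.any(null[:, i] < 0) else np.nan
        for i in range(n_sets)
    ])

    def norm_one(x, i):
        denom = pos_mean[i] if x >= 0 else neg_mean[i]
        return x / denom if np.isfinite(denom) and denom > 0 else np.nan

    nes_obs = np.array([norm_one(obs[i], i) for i in range(n_sets)])
    nes_null = np.array([
        [norm_one(null[b, i], i) for i in range(n_sets)]
        for b in range(null.shape[0])
    ])
    return nes_obs, nes_null


def _pooled_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """GSEA-style FDR: pooled null tail fraction over observed tail fraction."""
    flat = nes_null[np.isfinite(nes_null)]
    obs = nes_obs
    fdr = np.empty_like(obs)
    for i, x in enumerate(obs):
        if not np.isfinite(x):
            fdr[i] = np.nan
            continue
        if x >= 0:
            null_tail = np.mean(flat >= x) if flat.size else 1.0
            obs_tail = np.mean(obs[np.isfinite(obs)] >= x)
        else:
            null_tail = np.mean(flat <= x) if flat.size else 1.0
            obs_tail = np.mean(obs[np.isfinite(obs)] <= x)
        fdr[i] = min(1.0, null_tail / max(obs_tail, 1e-12))
    return fdr
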