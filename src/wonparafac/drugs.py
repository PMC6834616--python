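"""Per-compound elastic-net drug-response models on factor loadings.

For each compound, an elastic net (l1_ratio defaults to 0.5) maps
predictors — sample-factor loadings or raw molecular features — to AUC
drug-sensitivity values.  The penalty is chosen by 10-fold inner
cross-validation at minimum loss; honest performance comes from a nested
double-loop CV whose outer partition is a deterministic function of the
seed and sample count, so factor-based and raw-based runs are compared on
byte-identical folds.  Negative coefficients mark sensitivity factors
(lower AUC = more sensitive), positive ones resistance factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold


@dataclass
class DrugModel:
    compound: str
    coefficients: np.ndarray  # original predictor scale
    intercept: float
    alpha: float  # selected penalty strength (glmnet's lambda)
    l1_ratio: float
    cv_performance: float  # Pearson r, out-of-fold predictions vs observed
    n_selected: int
    predictor_names: list | None = None
    seed: int | None = None
    notes: list = field(default_factory=list)

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients)

    def predict(self, predictors: np.ndarray) -> np.ndarray:
        X = np.asarray(predictors, dtype=float)
        return self.intercept + X @ self.coefficients


def _drop_missing(X: np.ndarray, y: np.ndarray):
    keep = np.isfinite(y)
    return X[keep], y[keep], keep


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def fold_partition(n_samples: int, n_folds: int, seed: int | None):
    """The shared fold partition: a deterministic function of (n, folds, seed).

    Both the factor-predictor and raw-predictor pipelines call this, so a
    common seed guarantees identical fold memberships for fair comparison.
    """
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n_samples)))


def fit_drug_model(
    predictors: np.ndarray | pd.DataFrame,
    response: np.ndarray | pd.Series,
    compound: str = "drug",
    folds: int = 10,
    seed: int | None = None,
    l1_ratio: float = 0.5,
    alphas=None,
) -> DrugModel:
    """Elastic net for one compound; penalty by inner 10-fold CV.

    ``alphas`` overrides the CV penalty grid (e.g. a single near-zero
    value approximates ordinary least squares when p < n).

    Predictors are standardized internally (factor scales differ);
    coefficients are reported back on the original predictor scale.
    Samples with missing response are dropped.  A constant response yields
    an intercept-only model flagged in ``notes``.
    """
    names = list(predictors.columns) if isinstance(predictors, pd.DataFrame) else None
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(response, dtype=float)
    X, y, _ = _drop_missing(X, y)
    if y.size < 3 * folds:
        raise ValueError(f"need at least {3 * folds} observed samples, got {y.size}")
    if np.std(y) == 0:
        return DrugModel(compound=compound, coefficients=np.zeros(X.shape[1]),
                         intercept=float(y[0]) if y.size else 0.0, alpha=np.nan,
                         l1_ratio=l1_ratio, cv_performance=float("nan"),
                         n_selected=0, predictor_names=names, seed=seed,
                         notes=["constant response: intercept-only model"])
    Xs, mu, sd = _standardize(X)
    cv = fold_partition(y.size, folds, seed)
    en = ElasticNetCV(l1_ratio=l1_ratio, cv=cv,
                      alphas=50 if alphas is None else alphas, max_iter=10000)
    en.fit(Xs, y)
    # out-of-fold predictions at the selected penalty, same partition
    oof = np.empty_like(y)
    for tr, te in cv:
        m = ElasticNet(alpha=en.alpha_, l1_ratio=l1_ratio, max_iter=10000)
        m.fit(Xs[tr], y[tr])
        oof[te] = m.predict(Xs[te])
    coef = en.coef_ / sd
    intercept = float(en.intercept_ - np.dot(coef, mu))
    return DrugModel(compound=compound, coefficients=coef, intercept=intercept,
                     alpha=float(en.alpha_), l1_ratio=l1_ratio,
                     cv_performance=_pearson(oof, y),
                     n_selected=int(np.count_nonzero(coef)),
                     predictor_names=names, seed=seed)


def nested_cv_performance(
    predictors: np.ndarray | pd.DataFrame,
    response: np.ndarray | pd.Series,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int | None = None,
    l1_ratio: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Nested double-loop CV: outer folds held out, inner CV tunes the penalty.

    Returns the Pearson r between concatenated out-of-fold predictions
    and observations, and a per-sample frame (fold, observed, predicted).
    The outer partition depends only on (n, outer_folds, seed), so runs
    with different predictor matrices share it exactly.
    """
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(response, dtype=float)
    X, y, keep = _drop_missing(X, y)
    outer = fold_partition(y.size, outer_folds, seed)
    pred = np.full(y.size, np.nan)
    fold_of = np.full(y.size, -1)
    for f, (tr, te) in enumerate(outer):
        if np.std(y[tr]) == 0:
            continue  # zero-variance training fold: skip with NaN predictions
        Xs_tr, mu, sd = _standardize(X[tr])
        inner = fold_partition(tr.size, inner_folds, seed)
        en = ElasticNetCV(l1_ratio=l1_ratio, cv=inner, alphas=50, max_iter=10000)
        en.fit(Xs_tr, y[tr])
        pred[te] = en.predict((X[te] - mu) / sd)
        fold_of[te] = f
    ok = np.isfinite(pred)
    r = _pearson(pred[ok], y[ok])
    detail = pd.DataFrame({"fold": fold_of, "observed": y, "predicted": pred})
    detail.attrs["kept_mask"] = keep
    return r, detail


def factor_contributions(model: DrugModel, predictors: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Relative contribution of each predictor to the model's predictions.

    contribution_j = mean_i |beta_j x_ij|, normalized to sum 1 over the
    predictors with nonzero coefficients.
    """
    X = np.asarray(predictors, dtype=float)
    raw = np.mean(np.abs(X * model.coefficients), axis=0)
    raw[model.coefficients == 0] = 0.0
    tot = raw.sum()
    if tot <= 0:
        raise ValueError("model has no nonzero coefficient")
    return raw / tot


def sensitivity_partition(
    C: np.ndarray | pd.DataFrame,
    model: DrugModel,
    top_n: int = 5,
    tie: str = "resistant",
) -> dict:
    """Split samples into predicted-sensitive vs predicted-resistant groups.

    Among the union of the ``top_n`` largest-|coefficient| predictors,
    negative-coefficient factors are sensitivity factors and positive ones
    resistance factors; a sample is predicted sensitive when its summed
    loading on the sensitivity side exceeds the resistance side.  Ties go
    to the configured side.
    """
    X = np.asarray(C, dtype=float)
    beta = model.coefficients
    top = np.argsort(-np.abs(beta), kind="stable")[:top_n]
    top = top[beta[top] != 0]
    sens = top[beta[top] < 0]
    resi = top[beta[top] > 0]
    if sens.size == 0 or resi.size == 0:
        raise ValueError("one-sided coefficient set: partition unavailable")
    s_load = X[:, sens].sum(axis=1)
    r_load = X[:, resi].sum(axis=1)
    sensitive = s_load > r_load
    ties = s_load == r_load
    if tie == "sensitive":
        sensitive = sensitive | ties
    return {
        "sensitive": np.flatnonzero(sensitive),
        "resistant": np.flatnonzero(~sensitive),
        "sensitivity_factors": sens,
        "resistance_factors": resi,
        "n_ties": int(ties.sum()),
    }


def compare_predictor_spaces(
    factor_predictors,
    raw_predictors,
    responses: pd.DataFrame,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int | None = None,
    l1_ratio: float = 0.5,
) -> pd.DataFrame:
    """Nested-CV r for every compound in factor vs raw predictor space.

    Shares the outer partition between the two spaces per compound.
    Returns (compound, r_factor, r_raw, n).
    """
    rows = []
    for compound in responses.columns:
        y = responses[compound]
        r_f, _ = nested_cv_performance(factor_predictors, y, outer_folds,
                                       inner_folds, seed, l1_ratio)
        r_r, _ = nested_cv_performance(raw_predictors, y, outer_folds,
                                       inner_folds, seed, l1_ratio)
        rows.append({"compound": compound, "r_factor": r_f, "r_raw": r_r,
                     "n": int(np.isfinite(np.asarray(y, float)).sum())})
    return pd.DataFrame(rows)
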