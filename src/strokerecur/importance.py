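"""Importance-fusion recurrence score.

Two tree-ensemble classifiers — gradient-boosted trees (XGBoost) and a
random forest — are tuned by 10-fold cross-validated grid search on a 7:3
stratified split. Feature importance is read off each model's native lens:
mean absolute Shapley attribution (TreeSHAP, margin/log-odds units) from the
boosted model, mean impurity decrease (GINI) from the forest. The features
ranking in both models' top k (k = 5 by default) form the score, with per-
feature coefficient

    coef(f) = z(shap importance of f) + z(gini importance of f),

each z-score taken across the full feature set within its importance type.
A patient's recurrence score is the coefficient-weighted sum of their
(z-standardized continuous / integer-coded categorical) feature values, and
the score is dichotomized strictly above the cohort median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from ._rand import child_seed

__all__ = [
    "SplitSpec",
    "TunedModel",
    "DEFAULT_GRIDS",
    "split_cohort",
    "train_tuned_classifier",
    "shap_attributions",
    "shap_importance",
    "gini_importance",
    "importance_table",
    "select_common_top_k",
    "fuse_weights",
    "compute_scores",
    "run_pipeline",
    "PipelineResult",
]

OUTCOME = "recurrence_binary"


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0
    stratify_on_outcome: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")


def split_cohort(
    cohort: pd.DataFrame, spec: SplitSpec = SplitSpec(), outcome: str = OUTCOME
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split; |train| = round(fraction * n), half-even."""
    n = len(cohort)
    if n < 10:
        raise ValueError(f"cohort too small to split (n={n} < 10)")
    n_train = round(spec.train_fraction * n)
    strat = cohort[outcome] if spec.stratify_on_outcome else None
    train, test = train_test_split(
        cohort,
        train_size=n_train,
        stratify=strat,
        random_state=child_seed(spec.seed, "split"),
        shuffle=True,
    )
    return train, test


# ---------------------------------------------------------------------------
# tuned classifiers

# Grids enumerate ascending complexity; CV ties resolve to the earliest
# (smallest) grid point.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "gradient_boosted_trees": [
        {"n_estimators": 50, "max_depth": 2, "learning_rate": 0.1},
        {"n_estimators": 50, "max_depth": 3, "learning_rate": 0.1},
        {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1},
        {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    ],
    "random_forest": [
        {"n_estimators": 100, "max_depth": 4},
        {"n_estimators": 100, "max_depth": None},
        {"n_estimators": 200, "max_depth": 4},
        {"n_estimators": 200, "max_depth": None},
    ],
}


def _make_estimator(family: str, params: dict, seed: int):
    if family == "gradient_boosted_trees":
        return xgb.XGBClassifier(
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            **params,
        )
    if family == "random_forest":
        return RandomForestClassifier(n_jobs=1, random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class TunedModel:
    estimator: object
    family: str
    features: list[str]
    best_params: dict
    cv_results: pd.DataFrame

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        """Class-1 probability for each row."""
        return self.estimator.predict_proba(data.loc[:, self.features])[:, 1]


def train_tuned_classifier(
    train: pd.DataFrame,
    features: list[str],
    family: str,
    outcome: str = OUTCOME,
    cv_folds: int = 10,
    grid: list[dict] | None = None,
    seed: int = 0,
) -> TunedModel:
    """Grid search by mean CV AUC; refit the winning point on the full train set."""
    X = train.loc[:, features].astype(float)
    y = train[outcome].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("training set contains a single outcome class")
    if counts.min() < cv_folds:
        raise ValueError(
            f"need >= {cv_folds} patients per class for {cv_folds}-fold CV, "
            f"got class counts {counts.tolist()}"
        )
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=child_seed(seed, "cv"))
    est_seed = child_seed(seed, "xgb" if family == "gradient_boosted_trees" else "rf")
    rows = []
    best_idx, best_auc = 0, -np.inf
    for i, params in enumerate(grid):
        est = _make_estimator(family, params, est_seed)
        aucs = cross_val_score(est, X, y, cv=cv, scoring="roc_auc", n_jobs=1)
        mean_auc = float(aucs.mean())
        rows.append({**params, "mean_cv_auc": mean_auc, "sd_cv_auc": float(aucs.std(ddof=1))})
        if mean_auc > best_auc:  # strict: ties keep the earlier, simpler point
            best_idx, best_auc = i, mean_auc
    best = grid[best_idx]
    final = _make_estimator(family, best, est_seed)
    final.fit(X, y)
    return TunedModel(
        estimator=final,
        family=family,
        features=list(features),
        best_params=dict(best),
        cv_results=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# importances


def _get_booster(model) -> xgb.Booster:
    est = model.estimator if isinstance(model, TunedModel) else model
    if isinstance(est, xgb.XGBClassifier):
        return est.get_booster()
    if isinstance(est, xgb.Booster):
        return est
    raise TypeError(
        "Shapley attributions are computed with XGBoost's native TreeSHAP and "
        f"support xgboost models only; got {type(est).__name__}"
    )


def shap_attributions(model, data: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-patient TreeSHAP attributions (margin units) and base values.

    Each row's attributions plus its base value sum to the model's margin
    (log-odds) prediction — the local-accuracy contract.
    """
    features = model.features if isinstance(model, TunedModel) else list(data.columns)
    booster = _get_booster(model)
    dm = xgb.DMatrix(data.loc[:, features].astype(float), feature_names=features)
    contribs = booster.predict(dm, pred_contribs=True)
    return (
        pd.DataFrame(contribs[:, :-1], columns=features, index=data.index),
        contribs[:, -1],
    )


def shap_importance(model, data: pd.DataFrame) -> pd.Series:
    """Mean absolute Shapley attribution per feature (nonnegative)."""
    attr, _ = shap_attributions(model, data)
    return attr.abs().mean(axis=0).rename("shap_importance")


def gini_importance(model) -> pd.Series:
    """Mean impurity decrease per feature from a fitted forest."""
    est = model.estimator if isinstance(model, TunedModel) else model
    if not hasattr(est, "feature_importances_"):
        raise TypeError(f"{type(est).__name__} exposes no impurity importances")
    names = model.features if isinstance(model, TunedModel) else None
    if names is None:
        names = [f"f{i}" for i in range(len(est.feature_importances_))]
    return pd.Series(est.feature_importances_, index=names, name="gini_importance")


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    if sd == 0:
        # degenerate: all features equally important -> all z-scores 0
        return s * 0.0
    return (s - s.mean()) / sd


def importance_table(
    shap: pd.Series | None = None, gini: pd.Series | None = None
) -> pd.DataFrame:
    """Raw + standardized importance columns; z-scores taken across features."""
    if shap is None and gini is None:
        raise ValueError("need at least one importance vector")
    parts = {}
    if shap is not None:
        if (shap < 0).any():
            raise ValueError("raw importances must be nonnegative")
        parts["shap_importance"] = shap
        parts["shap_std"] = _zscore(shap)
    if gini is not None:
        if (gini < 0).any():
            raise ValueError("raw importances must be nonnegative")
        parts["gini_importance"] = gini
        parts["gini_std"] = _zscore(gini)
    return pd.DataFrame(parts)


def _raw_ranking(table: pd.DataFrame) -> pd.Series:
    for col in ("shap_importance", "gini_importance"):
        if col in table.columns and table[col].notna().all():
            return table[col]
    raise ValueError("importance table has no complete raw importance column")


def select_common_top_k(
    table_a: pd.DataFrame, table_b: pd.DataFrame, k: int = 5
) -> list[str]:
    """Features in both models' top-k by raw importance.

    Ordered by summed standardized importance (A's shap z + B's gini z)
    descending. The intersection may hold fewer than k features — or none,
    which warns rather than failing.
    """
    if set(table_a.index) != set(table_b.index):
        raise ValueError("importance tables cover different feature universes")
    top_a = set(_raw_ranking(table_a).nlargest(k).index)
    top_b = set(_raw_ranking(table_b).nlargest(k).index)
    common = top_a & top_b
    if not common:
        warnings.warn(f"no common features in the two top-{k} lists")
        return []
    combined = (table_a["shap_std"] + table_b["gini_std"]).loc[sorted(common)]
    return list(combined.sort_values(ascending=False).index)


def fuse_weights(
    table_a: pd.DataFrame, table_b: pd.DataFrame, features: list[str]
) -> pd.Series:
    """coef(f) = shap z-score (boosted model) + gini z-score (forest)."""
    missing = [f for f in features if f not in table_a.index or f not in table_b.index]
    if missing:
        raise KeyError(f"features absent from importance tables: {missing}")
    coef = table_a.loc[features, "shap_std"] + table_b.loc[features, "gini_std"]
    return coef.rename("coef")


def compute_scores(
    cohort: pd.DataFrame,
    weights: pd.Series,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Recurrence score per patient and its strict-median dichotomization.

    Continuous features are z-standardized on the full cohort before
    weighting; ordinal/binary features enter as integer codes. Returns a
    frame with `score` and `score_code` (1 iff score > cohort median).
    """
    missing = [f for f in weights.index if f not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks weighted features: {missing}")
    X = cohort.loc[:, list(weights.index)].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing feature values in {bad}; no imputation is performed")
    for c in continuous or []:
        if c in X.columns:
            sd = X[c].std(ddof=0)
            X[c] = (X[c] - X[c].mean()) / sd if sd > 0 else 0.0
    score = X.to_numpy() @ weights.to_numpy(dtype=float)
    median = float(np.median(score)) if len(score) else float("nan")
    return pd.DataFrame(
        {"score": score, "score_code": (score > median).astype(int)}, index=cohort.index
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    train: pd.DataFrame
    test: pd.DataFrame
    xgb_model: TunedModel
    rf_model: TunedModel
    table_xgb: pd.DataFrame
    table_rf: pd.DataFrame
    common_features: list[str]
    weights: pd.Series
    scores: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def run_pipeline(
    cohort: pd.DataFrame,
    features: list[str],
    outcome: str = OUTCOME,
    continuous: list[str] | None = None,
    seed: int = 0,
    k: int = 5,
    cv_folds: int = 10,
    grids: dict[str, list[dict]] | None = None,
    shap_data: str = "train",
) -> PipelineResult:
    """Split, tune both families, fuse importances, and score the cohort.

    shap_data selects whether Shapley attributions are summarized on the
    training or the test split.
    """
    from .metrics import evaluate_model

    grids = grids or DEFAULT_GRIDS
    train, test = split_cohort(cohort, SplitSpec(seed=seed), outcome=outcome)
    xgb_model = train_tuned_classifier(
        train, features, "gradient_boosted_trees", outcome, cv_folds,
        grids.get("gradient_boosted_trees"), seed,
    )
    rf_model = train_tuned_classifier(
        train, features, "random_forest", outcome, cv_folds,
        grids.get("random_forest"), seed,
    )
    shap_src = train if shap_data == "train" else test
    table_xgb = importance_table(shap=shap_importance(xgb_model, shap_src))
    table_rf = importance_table(gini=gini_importance(rf_model))
    common = select_common_top_k(table_xgb, table_rf, k=k)
    weights = fuse_weights(table_xgb, table_rf, common) if common else pd.Series(dtype=float)
    scores = (
        compute_scores(cohort, weights, continuous=continuous)
        if len(weights)
        else pd.DataFrame({"score": np.zeros(len(cohort)), "score_code": 0}, index=cohort.index)
    )
    y_test = test[outcome].to_numpy(dtype=int)
    metrics = {
        "gradient_boosted_trees": evaluate_model(xgb_model.predict_proba(test), y_test),
        "random_forest": evaluate_model(rf_model.predict_proba(test), y_test),
    }
    return PipelineResult(
        train=train,
        test=test,
        xgb_model=xgb_model,
        rf_model=rf_model,
        table_xgb=table_xgb,
        table_rf=table_rf,
        common_features=common,
        weights=weights,
        scores=scores,
        metrics=metrics,
    )
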