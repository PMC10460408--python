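"""Stage-1 outcome models: fit, evaluate, select, rank features.

Four model families (logistic regression, gradient boosting, random forest,
and a one-hidden-layer feed-forward network) are fitted to a binary target.
Evaluation follows a stratified 70/30 holdout: 10-fold stratified
cross-validation runs inside the 70% training split (per-fold metrics are
reported, and any list-valued hyperparameter is selected there by mean CV
AUC), the model is refitted on the full training split, and the reported
accuracy/AUC come from the untouched 30% holdout.  The family with the
highest holdout AUC wins.

Feature importance is model-agnostic permutation importance: permute one
schema-level variable at a time (all of its one-hot columns move together),
measure the holdout AUC drop, average over repeats, and scale by the
maximum so the top variable scores exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from ._encode import CohortEncoder
from .schema import CohortSchema, CohortTable, SchemaError, ValidationError

__all__ = [
    "FAMILY_ORDER",
    "ModelSpec",
    "EvaluationRecord",
    "FittedOutcomeModel",
    "ImportanceTable",
    "auc",
    "accuracy",
    "default_specs",
    "fit_and_evaluate",
    "fit_full",
    "select_best",
    "feature_importance",
]

logger = logging.getLogger(__name__)

#: Declared family order; also the tie-break order in :func:`select_best`.
FAMILY_ORDER = (
    "logistic_regression",
    "gradient_boosting",
    "random_forest",
    "feedforward_net",
)


@dataclass(frozen=True)
class ModelSpec:
    """One model family plus hyperparameters and its seed.

    A list-valued hyperparameter denotes a (small) grid to be selected over
    by mean cross-validated AUC within the training split.
    """

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILY_ORDER:
            raise ValueError(f"unknown model family {self.family!r}; known: {FAMILY_ORDER}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))


@dataclass
class EvaluationRecord:
    """Holdout + cross-validation performance for one family."""

    family: str
    accuracy: float
    auc: float
    split_seed: int
    cv_fold_metrics: list[dict]
    chosen_hyperparameters: dict
    cv_mean_auc: float

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "holdout_accuracy": self.accuracy,
            "holdout_auc": self.auc,
            "cv_mean_auc": self.cv_mean_auc,
            "split_seed": self.split_seed,
            "chosen_hyperparameters": self.chosen_hyperparameters,
            "cv_fold_metrics": self.cv_fold_metrics,
        }


@dataclass
class FittedOutcomeModel:
    """A trained probability-of-outcome predictor bound to its schema."""

    spec: ModelSpec
    target: str
    estimator: object
    encoder: CohortEncoder
    training_schema: CohortSchema

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        """P(target = 1) for each row of ``table``."""
        if [v.name for v in table.schema.predictors()] != [
            v.name for v in self.training_schema.predictors()
        ]:
            raise SchemaError("table predictors do not match the model's training schema")
        X = self.encoder.transform(table)
        p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)


@dataclass
class ImportanceTable:
    """Per-variable importance, scaled so the maximum is exactly 1."""

    entries: list[tuple[str, float, float]]  # (feature, raw, scaled), sorted desc

    @classmethod
    def from_raw(cls, raw: Mapping[str, float]) -> "ImportanceTable":
        clipped = {k: max(0.0, float(v)) for k, v in raw.items()}
        top = max(clipped.values()) if clipped else 0.0
        scaled = {k: (v / top if top > 0 else 0.0) for k, v in clipped.items()}
        entries = sorted(
            ((k, clipped[k], scaled[k]) for k in clipped),
            key=lambda e: (-e[2], e[0]),
        )
        return cls(entries)

    def top(self, k: int) -> list[str]:
        return [name for name, _, _ in self.entries[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "raw_score", "scaled_score"])


# -- metrics ------------------------------------------------------------------


def auc(labels: Sequence[float], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals P(score of a random positive > score of a random negative) plus
    half the tie probability.  Both classes must be present.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D vectors")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def accuracy(labels: Sequence[float], scores: Sequence[float], threshold: float = 0.5) -> float:
    """Fraction correct when classifying as 1 iff score >= threshold."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    return float(np.mean((s >= threshold) == (y == 1)))


# -- estimator construction ---------------------------------------------------


def _build_estimator(spec: ModelSpec, hp: Mapping[str, object], n_features: int):
    if spec.family == "logistic_regression":
        params = {"max_iter": 5000, "C": 1.0, **hp}
        return make_pipeline(StandardScaler(), LogisticRegression(**params))
    if spec.family == "gradient_boosting":
        params = {"n_estimators": 100, "max_depth": 3, "random_state": spec.seed, **hp}
        return GradientBoostingClassifier(**params)
    if spec.family == "random_forest":
        # conservative leaf size (fraction of n): counterfactual differences
        # inherit any noise the forest memorises, so smoothness matters more
        # here than in a pure prediction setting
        params = {
            "n_estimators": 500,
            "min_samples_leaf": 0.03,
            "random_state": spec.seed,
            **hp,
        }
        return RandomForestClassifier(**params)
    # feedforward_net: smallest architecture sensible for small tabular data —
    # one hidden layer of width max(8, n_features), early stopping.
    params = {
        "hidden_layer_sizes": (max(8, n_features),),
        "early_stopping": True,
        "max_iter": 400,
        "random_state": spec.seed,
        **hp,
    }
    return make_pipeline(StandardScaler(), MLPClassifier(**params))


def _hyperparameter_grid(hp: Mapping[str, object]) -> list[dict]:
    keys = [k for k, v in hp.items() if isinstance(v, (list, tuple))]
    if not keys:
        return [dict(hp)]
    fixed = {k: v for k, v in hp.items() if k not in keys}
    grids = []
    for combo in product(*(hp[k] for k in keys)):
        grids.append({**fixed, **dict(zip(keys, combo))})
    return grids


# -- fitting and evaluation ---------------------------------------------------


@dataclass
class StageOneResult:
    """Everything stage 1 produces for one target."""

    target: str
    records: list[EvaluationRecord]
    models: dict[str, FittedOutcomeModel]
    train_idx: np.ndarray
    test_idx: np.ndarray

    def best_family(self) -> str:
        return select_best(self.records)

    def best_model(self) -> FittedOutcomeModel:
        return self.models[self.best_family()]


def default_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(family, seed=seed) for family in FAMILY_ORDER]


def fit_and_evaluate(
    table: CohortTable,
    target: str,
    specs: Sequence[ModelSpec],
    split_seed: int,
    test_fraction: float = 0.3,
    n_folds: int = 10,
) -> StageOneResult:
    """Fit every spec on a stratified 70/30 split and score the holdout.

    Ten-fold stratified CV runs inside the training split (fold metrics are
    recorded; list-valued hyperparameters are chosen by mean CV AUC); the
    chosen configuration is refitted on the full training split and scored
    on the untouched holdout.
    """
    if table.n < 20:
        raise ValidationError(f"need at least 20 rows to split and cross-validate, got {table.n}")
    spec_t = table.schema[target]
    if spec_t.role != "target" or spec_t.vtype != "binary":
        raise ValidationError(f"{target!r} is not a binary target variable")
    y = table.df[target].to_numpy(dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError(f"target {target!r} has a single class; cannot evaluate")

    idx = np.arange(table.n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=split_seed, stratify=y
    )
    encoder = CohortEncoder().fit(table, train_idx)
    X = encoder.transform(table)
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]

    records: list[EvaluationRecord] = []
    models: dict[str, FittedOutcomeModel] = {}
    for spec in specs:
        best_hp, best_cv_auc, best_folds = None, -np.inf, []
        for hp in _hyperparameter_grid(spec.hyperparameters):
            folds = []
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
            for k, (tr, va) in enumerate(skf.split(X_tr, y_tr)):
                est = _build_estimator(spec, hp, X.shape[1])
                est.fit(X_tr[tr], y_tr[tr])
                p = est.predict_proba(X_tr[va])[:, 1]
                folds.append(
                    {"fold": k, "auc": auc(y_tr[va], p), "accuracy": accuracy(y_tr[va], p)}
                )
            mean_auc = float(np.mean([f["auc"] for f in folds]))
            if mean_auc > best_cv_auc:
                best_hp, best_cv_auc, best_folds = hp, mean_auc, folds
        est = _build_estimator(spec, best_hp, X.shape[1])
        est.fit(X_tr, y_tr)
        p_te = est.predict_proba(X_te)[:, 1]
        rec = EvaluationRecord(
            family=spec.family,
            accuracy=accuracy(y_te, p_te),
            auc=auc(y_te, p_te),
            split_seed=split_seed,
            cv_fold_metrics=best_folds,
            chosen_hyperparameters=best_hp,
            cv_mean_auc=best_cv_auc,
        )
        records.append(rec)
        models[spec.family] = FittedOutcomeModel(
            spec=spec,
            target=target,
            estimator=est,
            encoder=encoder,
            training_schema=table.schema,
        )
        logger.info(
            "stage1 %s/%s: holdout AUC %.3f, accuracy %.3f (CV mean AUC %.3f)",
            target, spec.family, rec.auc, rec.accuracy, best_cv_auc,
        )
    return StageOneResult(target, records, models, train_idx, test_idx)


def fit_full(table: CohortTable, target: str, spec: ModelSpec) -> FittedOutcomeModel:
    """Refit one family on the entire cohort (no holdout).

    Used before the counterfactual stage, where prediction stability matters
    more than an unbiased performance estimate.
    """
    y = table.df[target].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError(f"target {target!r} has a single class")
    encoder = CohortEncoder().fit(table)
    X = encoder.transform(table)
    est = _build_estimator(spec, _hyperparameter_grid(spec.hyperparameters)[0], X.shape[1])
    est.fit(X, y)
    return FittedOutcomeModel(spec, target, est, encoder, table.schema)


def select_best(records: Sequence[EvaluationRecord]) -> str:
    """Family with the highest holdout AUC; ties go to declared family order."""
    if not records:
        raise ValueError("no evaluation records to select from")
    best = max(records, key=lambda r: (r.auc, -FAMILY_ORDER.index(r.family)))
    ties = [r.family for r in records if r.auc == best.auc]
    if len(ties) > 1:
        logger.warning("AUC tie among %s; choosing %s by declared order", ties, best.family)
    return best.family


def feature_importance(
    model: FittedOutcomeModel,
    table: CohortTable,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """Permutation importance of each schema variable, scaled to max 1.

    For each predictor the raw column is permuted (n_repeats shuffles; all
    one-hot columns derived from it move together because the permuted table
    is re-encoded) and the mean drop in AUC on ``table`` is recorded as the
    raw score.  Negative drops clip to zero.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = table.df[model.target].to_numpy(dtype=float)
    base = auc(y, model.predict_proba(table))
    df = table.df
    predictors = table.schema.predictors()
    # stack every permuted copy into one table so the (possibly large)
    # ensemble predicts once instead of n_predictors * n_repeats times
    blocks = []
    for spec in predictors:
        for _ in range(n_repeats):
            perm = df.copy()
            perm[spec.name] = df[spec.name].to_numpy()[rng.permutation(table.n)]
            blocks.append(perm)
    stacked = CohortTable(
        pd.concat(blocks, ignore_index=True), table.schema, validate=False
    )
    p = model.predict_proba(stacked).reshape(len(predictors), n_repeats, table.n)
    raw = {
        spec.name: float(np.mean([base - auc(y, p[i, r]) for r in range(n_repeats)]))
        for i, spec in enumerate(predictors)
    }
    return ImportanceTable.from_raw(raw)
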