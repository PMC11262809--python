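"""Final classifier, cross-validated evaluation, importance and ranking.

The default final model is a random forest (100 trees, sqrt features per
split) trained on the 2j+2 pair score vectors; logistic regression,
decision tree, k-nearest-neighbor and two small MLPs are available as
drop-in alternatives. Evaluation is stratified 5-fold cross-validation
reporting AUROC, AUPR, accuracy, precision, recall and F1.

Leakage control: within each fold the association index is rebuilt from
that fold's training positives only, and both train and test pairs are
featurized against it. A test positive therefore contributes nothing to
its own evidence sets and is scored exactly as an unknown pair would be.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .data import AssociationIndex
from .scoring import build_design_matrix
from .similarity import FeatureSimilarities

__all__ = [
    "ClassifierSpec",
    "make_classifier",
    "train_classifier",
    "compute_metrics",
    "EvaluationReport",
    "cross_validate",
    "feature_importance",
    "incremental_feature_evaluation",
    "rank_candidates",
]

METRIC_NAMES = ("auroc", "aupr", "accuracy", "precision", "recall", "f1")

# Random-forest defaults: 100 trees, unlimited depth, sqrt-features per
# split. Exposed so runs can sweep them; results are robust to moderate
# changes.
RF_DEFAULTS = {"n_estimators": 100, "max_depth": None, "max_features": "sqrt"}


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier plus parameter overrides and a seed."""

    name: str = "random_forest"
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def make_classifier(spec: ClassifierSpec):
    """Instantiate a scikit-learn classifier from a spec."""
    params = dict(spec.parameters)
    if spec.name == "random_forest":
        merged = {**RF_DEFAULTS, **params}
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **merged)
    if spec.name == "logistic_regression":
        return LogisticRegression(random_state=spec.seed, max_iter=1000, **params)
    if spec.name == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    if spec.name == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 5, **params})
    if spec.name == "mlp":
        # two hidden layers (32, 64) by default; pass (32, 64, 128) for the deeper variant
        merged = {"hidden_layer_sizes": (32, 64), "activation": "relu", "max_iter": 500, **params}
        return MLPClassifier(random_state=spec.seed, **merged)
    raise ValueError(f"unknown classifier {spec.name!r}")


def train_classifier(X, y, spec: ClassifierSpec = ClassifierSpec()):
    """Fit the classifier; both classes must be present."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class {classes}; need both 0 and 1")
    model = make_classifier(spec)
    model.fit(X, y)
    return model


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """AUROC, AUPR and the four thresholded metrics.

    AUROC is the probability a random positive outranks a random negative
    (ties counted half); AUPR is step-wise precision-recall summation
    (average precision). Thresholded metrics use ``score >= threshold``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC/AUPR are undefined with a single class")
    preds = (scores >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "accuracy": float(accuracy_score(labels, preds)),
        "precision": float(precision_score(labels, preds, zero_division=0)),
        "recall": float(recall_score(labels, preds, zero_division=0)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and mean metrics from cross-validation."""

    per_fold: tuple[dict[str, float], ...]

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    @property
    def aggregate(self) -> dict[str, float]:
        return {m: float(np.mean([f[m] for f in self.per_fold])) for m in METRIC_NAMES}

    def __getattr__(self, name: str) -> float:
        if name in METRIC_NAMES:
            return self.aggregate[name]
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i + 1, **f) for i, f in enumerate(self.per_fold)]
        rows.append(dict(fold="mean", **self.aggregate))
        return pd.DataFrame(rows)


def cross_validate(
    pairs,
    labels,
    sims: FeatureSimilarities,
    spec: ClassifierSpec = ClassifierSpec(),
    n_folds: int = 5,
    seed: int = 0,
    mask_self: bool = True,
    slots=None,
) -> EvaluationReport:
    """Stratified k-fold evaluation with fold-restricted featurization.

    ``pairs`` mixes positives (label 1) and mined negatives (label 0).
    Each fold rebuilds the association index from its training-fold
    positives, featurizes both sides against it, trains, and scores the
    held-out pairs. ``slots`` optionally restricts the design matrix to a
    subset of named columns (used by incremental feature evaluation).
    """
    pairs = [(str(d), str(s)) for d, s in pairs]
    labels = np.asarray(labels, dtype=int)
    if len(pairs) != len(labels):
        raise ValueError("pairs and labels differ in length")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(pairs)), labels):
        train_pairs = [pairs[i] for i in train_idx]
        test_pairs = [pairs[i] for i in test_idx]
        y_train, y_test = labels[train_idx], labels[test_idx]
        if len(np.unique(y_test)) < 2 or len(np.unique(y_train)) < 2:
            raise ValueError("a fold contains a single class; use more data or fewer folds")
        fold_index = AssociationIndex.from_pairs(
            p for p, y in zip(train_pairs, y_train) if y == 1
        )
        X_train = build_design_matrix(train_pairs, sims, fold_index, mask_self=mask_self)
        X_test = build_design_matrix(test_pairs, sims, fold_index, mask_self=mask_self)
        if slots is not None:
            # keep canonical column order: the subset chooses membership only,
            # so the all-slots subset is bit-identical to the full model
            keep = [c for c in X_train.columns if c in set(slots)]
            missing = set(slots) - set(keep)
            if missing:
                raise KeyError(f"unknown slots {sorted(missing)}")
            X_train, X_test = X_train[keep], X_test[keep]
        model = train_classifier(X_train.values, y_train, spec)
        scores = model.predict_proba(X_test.values)[:, 1]
        reports.append(compute_metrics(y_test, scores))
    return EvaluationReport(per_fold=tuple(reports))


def feature_importance(model, slot_names) -> list[tuple[str, float]]:
    """Normalized mean-decrease-in-impurity ranking, descending.

    Only tree-based models expose impurity importances; ties break
    lexicographically by slot name for determinism.
    """
    if not hasattr(model, "feature_importances_"):
        raise TypeError(f"{type(model).__name__} does not expose impurity-based feature importances")
    imp = np.asarray(model.feature_importances_, dtype=float)
    if len(imp) != len(slot_names):
        raise ValueError("slot name count does not match model feature count")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = sorted(range(len(imp)), key=lambda i: (-imp[i], slot_names[i]))
    return [(slot_names[i], float(imp[i])) for i in order]


def incremental_feature_evaluation(
    pairs,
    labels,
    sims: FeatureSimilarities,
    ranking,
    spec: ClassifierSpec = ClassifierSpec(),
    n_folds: int = 5,
    seed: int = 0,
    mask_self: bool = True,
) -> pd.DataFrame:
    """Metrics for growing top-n feature subsets of an importance ranking.

    Row i uses the top i+1 slots; the final row uses all slots and equals
    a full-model :func:`cross_validate` run at the same seed.
    """
    ranked_slots = [name for name, _ in ranking]
    expected = set(sims.catalog.slot_names())
    if set(ranked_slots) != expected:
        raise ValueError("ranking must cover every slot exactly once")
    rows = []
    for n in range(1, len(ranked_slots) + 1):
        subset = ranked_slots[:n]
        report = cross_validate(
            pairs, labels, sims, spec, n_folds=n_folds, seed=seed, mask_self=mask_self, slots=subset
        )
        rows.append({"n_features": n, "slot_added": ranked_slots[n - 1], **report.aggregate})
    return pd.DataFrame(rows)


def rank_candidates(
    model,
    sims: FeatureSimilarities,
    index: AssociationIndex,
    disease_id: str | None = None,
    drug_id: str | None = None,
    top_k: int | None = None,
    mask_self: bool = True,
) -> pd.DataFrame:
    """Rank unlabeled partners of one query entity by predicted probability.

    Known positives are excluded from the candidate list; ties break
    lexicographically by ids. Used for case-study style repositioning:
    score every unlabeled pair involving the query and read off the top
    candidates.
    """
    if (disease_id is None) == (drug_id is None):
        raise ValueError("provide exactly one of disease_id or drug_id")
    if disease_id is not None:
        if disease_id not in sims.disease_ids:
            raise KeyError(f"unknown disease id {disease_id!r}")
        candidates = [(d, disease_id) for d in sims.drug_ids if (d, disease_id) not in index]
    else:
        if drug_id not in sims.drug_ids:
            raise KeyError(f"unknown drug id {drug_id!r}")
        candidates = [(drug_id, s) for s in sims.disease_ids if (drug_id, s) not in index]
    if not candidates:
        return pd.DataFrame(columns=["drug_id", "disease_id", "score"])
    X = build_design_matrix(candidates, sims, index, mask_self=mask_self)
    scores = model.predict_proba(X.values)[:, 1]
    frame = pd.DataFrame(candidates, columns=["drug_id", "disease_id"])
    frame["score"] = scores
    frame = frame.sort_values(
        by=["score", "drug_id", "disease_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        frame = frame.head(top_k)
    return frame
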