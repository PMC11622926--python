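"""Data splitting, the gradient-boosted classification stage, and metrics.

The boosted stage is XGBoost configured with the study's hyperparameter
contract (logistic loss, learning rate 0.1, max depth 6, L2 penalty 1,
L1 penalty 0.5, logloss early stopping after 10 stale rounds). Evaluation
statistics are computed from the confusion counts: accuracy, precision
(positive predictive value), recall, specificity, F1, and Cohen's kappa.
The positive label defaults to 1 = disease.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ValidationError
from .preprocessing import FeatureTable

__all__ = [
    "BoostParams",
    "SplitPlan",
    "MetricsReport",
    "BoostedModel",
    "split_80_20",
    "kfold_5",
    "train_boosted",
    "confusion_counts",
    "compute_metrics",
    "cohen_kappa",
]


@dataclass
class BoostParams:
    """Hyperparameters of the boosted-tree stage."""

    learning_rate: float = 0.1
    max_depth: int = 6
    l2_penalty: float = 1.0
    l1_penalty: float = 0.5
    leaf_penalty: float = 0.0
    n_rounds: int = 100
    early_stopping_rounds: int = 10
    eval_metric: str = "logloss"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if min(self.l2_penalty, self.l1_penalty, self.leaf_penalty) < 0:
            raise ValidationError("penalties must be >= 0")
        if self.n_rounds < 1:
            raise ValidationError("n_rounds must be >= 1")


@dataclass
class SplitPlan:
    """Train/test indices, optionally with stratified folds over the train part."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    folds: Optional[list[tuple[np.ndarray, np.ndarray]]] = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_indices": self.train_indices.tolist(),
                "test_indices": self.test_indices.tolist(),
                "folds": None
                if self.folds is None
                else [[f.tolist(), v.tolist()] for f, v in self.folds],
                "seed": self.seed,
            }
        )


def split_80_20(n: int, labels: np.ndarray, seed: int = 0) -> SplitPlan:
    """Seeded stratified split with |test| = round(0.2 * n)."""
    labels = np.asarray(labels)
    if n < 5:
        raise ValidationError("need at least 5 samples for an 80/20 split")
    if labels.shape[0] != n:
        raise ValidationError("labels length must equal n")
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")
    n_test = int(round(0.2 * n))
    train_idx, test_idx = train_test_split(
        np.arange(n), test_size=n_test, stratify=labels, random_state=seed
    )
    return SplitPlan(np.sort(train_idx), np.sort(test_idx), seed=seed)


def kfold_5(
    train_indices: np.ndarray, labels: np.ndarray, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Five stratified (fit, validate) index pairs partitioning the train part.

    ``labels`` is indexed by absolute position, so ``labels[train_indices]``
    are the labels stratified over. Returned indices are absolute.
    """
    train_indices = np.asarray(train_indices)
    if train_indices.size < 5:
        raise ValidationError("need at least 5 training samples for 5 folds")
    y = np.asarray(labels)[train_indices]
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    return [
        (train_indices[fit], train_indices[val])
        for fit, val in skf.split(np.zeros(train_indices.size), y)
    ]


class BoostedModel:
    """Thin handle over a fitted XGBoost classifier."""

    def __init__(self, clf: xgb.XGBClassifier):
        self._clf = clf

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class (label 1)."""
        return self._clf.predict_proba(np.atleast_2d(X))[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class prediction: 1 when P(class 1) > 0.5."""
        return (self.predict_proba(X) > 0.5).astype(int)

    @property
    def n_rounds_used(self) -> int:
        booster = self._clf.get_booster()
        best = getattr(self._clf, "best_iteration", None)
        if best is not None:
            return int(best) + 1
        return booster.num_boosted_rounds()

    def save(self, path) -> None:
        self._clf.save_model(str(path))


def _extract_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, FeatureTable):
        if data.target is None:
            raise ValidationError("training table must carry a target")
        return data.values, data.target
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y)


def train_boosted(
    train, params: Optional[BoostParams] = None, validation=None
) -> BoostedModel:
    """Fit the boosted-tree classifier under the stated hyperparameters.

    ``train`` is a FeatureTable with target or an (X, y) pair; ``validation``
    likewise, and when supplied enables logloss early stopping.
    """
    params = params or BoostParams()
    X, y = _extract_xy(train)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    kwargs = dict(
        n_estimators=params.n_rounds,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        reg_lambda=params.l2_penalty,
        reg_alpha=params.l1_penalty,
        gamma=params.leaf_penalty,
        eval_metric=params.eval_metric,
        n_jobs=1,
        random_state=0,
        tree_method="hist",
    )
    if validation is not None:
        kwargs["early_stopping_rounds"] = params.early_stopping_rounds
    clf = xgb.XGBClassifier(**kwargs)
    if validation is not None:
        Xv, yv = _extract_xy(validation)
        clf.fit(X, y, eval_set=[(Xv, yv)], verbose=False)
    else:
        clf.fit(X, y)
    return BoostedModel(clf)


def confusion_counts(
    truth: Sequence[int], predicted: Sequence[int], positive_label: int = 1
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with respect to ``positive_label`` (default 1 = disease)."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValidationError("truth and predicted must have equal length")
    if t.size and (not np.isin(t, (0, 1)).all() or not np.isin(p, (0, 1)).all()):
        raise ValidationError("entries must be binary {0,1}")
    pos_t = t == positive_label
    pos_p = p == positive_label
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    return tp, fp, tn, fn


@dataclass
class MetricsReport:
    """Confusion counts plus all derived rates for one evaluation.

    Rates whose defining denominator is zero are reported as 0 and flagged
    in ``undefined``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    kappa: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: tuple[int, int, int, int]) -> MetricsReport:
    """All rates from (TP, FP, TN, FN).

    accuracy = (TP+TN)/n, precision = TP/(TP+FP), recall = TP/(TP+FN),
    specificity = TN/(TN+FP), F1 = 2PR/(P+R); kappa from the table marginals.
    """
    tp, fp, tn, fn = (int(c) for c in counts)
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn < 1:
        raise ValidationError("counts must be nonnegative with a positive total")
    undefined: list[str] = []
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    precision = _ratio(tp, tp + fp, "precision", undefined)
    recall = _ratio(tp, tp + fn, "recall", undefined)
    specificity = _ratio(tn, tn + fp, "specificity", undefined)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", undefined)
    kappa = _kappa_from_counts(tp, fp, tn, fn)
    return MetricsReport(
        tp, fp, tn, fn, accuracy, precision, recall, specificity, f1, kappa,
        undefined,
    )


def _kappa_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    n = tp + fp + tn + fn
    observed = (tp + tn) / n
    # marginals: truth rows (pos, neg), prediction columns (pos, neg)
    truth_pos, truth_neg = tp + fn, fp + tn
    pred_pos, pred_neg = tp + fp, fn + tn
    expected = (truth_pos * pred_pos + truth_neg * pred_neg) / (n * n)
    if expected == 1.0:
        return 1.0 if observed == 1.0 else 0.0
    return (observed - expected) / (1.0 - expected)


def cohen_kappa(truth: Sequence[int], predicted: Sequence[int]) -> float:
    """Chance-corrected agreement (observed - expected) / (1 - expected)."""
    tp, fp, tn, fn = confusion_counts(truth, predicted)
    return _kappa_from_counts(tp, fp, tn, fn)
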