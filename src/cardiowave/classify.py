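"""Grid-search-tuned classical classifiers and validation schemes.

Four model families are supported — decision tree (DT), random forest
(RF), multi-layer perceptron (MLP), and gradient-boosted trees (XGB) —
each tuned by exhaustive grid search scored with inner k-fold accuracy.
Two evaluation schemes mirror how segment-level physiological
classifiers are normally validated:

* leave-one-subject-out (LOSO): all segments of one subject form the
  test fold, so subject identity can never leak into training; the
  pooled confusion over all held-out segments is reported;
* leave-data-out (LDO): a stratified segment-level hold-out split,
  which does allow subject overlap between sides and therefore gives
  systematically optimistic numbers on subject-structured data.

Metrics are precision, recall, F1 and accuracy from the confusion
counts; multi-class metrics are per-class one-vs-rest.  A zero
denominator (e.g. precision with no positive predictions) reports 0
with a logged warning.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .exceptions import (
    DataLeakError,
    DegenerateSplitError,
    InvalidArgumentError,
    InvalidFamilyError,
)
from .feature_select import FeatureTable, elastic_net_select

logger = logging.getLogger(__name__)

FAMILIES = ("DT", "RF", "MLP", "XGB")

#: Default hyper-parameter grids per family.
DEFAULT_GRIDS: dict[str, dict] = {
    "DT": {"max_depth": [3, 5, 10, None], "min_samples_split": [2, 5, 10]},
    "RF": {"n_estimators": [100, 300, 500], "max_depth": [5, 10, None]},
    "MLP": {"hidden_layer_sizes": [(64,), (128, 64)], "learning_rate_init": [1e-3, 1e-4]},
    "XGB": {"n_estimators": [100, 300], "max_depth": [3, 6], "learning_rate": [0.05, 0.1]},
}

#: One-point grids for quick, non-tuned fits.
FAST_GRIDS: dict[str, dict] = {
    "DT": {"max_depth": [None]},
    "RF": {"n_estimators": [200]},
    "MLP": {"hidden_layer_sizes": [(64,)]},
    "XGB": {"n_estimators": [100], "max_depth": [3]},
}


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Binary TP/FP/TN/FN or a K x K count matrix with class names.

    ``matrix[i, j]`` counts segments of true class ``classes[i]``
    predicted as ``classes[j]``.
    """

    matrix: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.classes):
            raise InvalidArgumentError("confusion matrix must be K x K with K class names")
        if (m < 0).any():
            raise InvalidArgumentError("confusion counts must be non-negative")

    @classmethod
    def binary(cls, tp: int, fp: int, tn: int, fn: int,
               positive: str = "AS", negative: str = "NON_AS") -> "ConfusionCounts":
        return cls(matrix=np.array([[tp, fn], [fp, tn]]), classes=(positive, negative))

    @classmethod
    def from_predictions(cls, truths: Sequence[str], preds: Sequence[str],
                         classes: Sequence[str] | None = None) -> "ConfusionCounts":
        labels = tuple(classes) if classes else tuple(sorted(set(truths) | set(preds)))
        pos = {c: i for i, c in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(truths, preds):
            m[pos[t], pos[p]] += 1
        return cls(matrix=m, classes=labels)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    scheme: str                               # LOSO | LEAVE_DATA_OUT | KFOLD
    per_class: dict[str, dict[str, float]]    # class -> precision/recall/f1
    accuracy: float
    confusion: ConfusionCounts
    model_family: str
    best_params: dict
    seed: int
    truths: tuple[str, ...] = ()
    predictions: tuple[str, ...] = ()
    extras: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "model_family": self.model_family,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion": {
                "classes": list(self.confusion.classes),
                "matrix": self.confusion.matrix.tolist(),
            },
            "best_params": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in self.best_params.items()},
            "seed": self.seed,
            "extras": self.extras,
        }


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0 by convention", what)
        return 0.0
    return num / den


def compute_metrics(confusion: ConfusionCounts) -> dict:
    """Per-class precision/recall/F1 (one-vs-rest) plus overall accuracy."""
    m = confusion.matrix.astype(float)
    if m.sum() == 0:
        raise InvalidArgumentError("empty confusion matrix")
    per_class = {}
    for i, cls in enumerate(confusion.classes):
        tp = m[i, i]
        fp = m[:, i].sum() - tp
        fn = m[i, :].sum() - tp
        precision = _safe_ratio(tp, tp + fp, f"precision[{cls}]")
        recall = _safe_ratio(tp, tp + fn, f"recall[{cls}]")
        f1 = _safe_ratio(2 * precision * recall, precision + recall, f"F1[{cls}]")
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
    accuracy = float(np.trace(m) / m.sum())
    return {"per_class": per_class, "accuracy": accuracy}


def _make_estimator(family: str, params: Mapping, seed: int, n_classes: int):
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "MLP":
        return MLPClassifier(random_state=seed, max_iter=500, **params)
    if family == "XGB":
        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist",
            objective="binary:logistic" if n_classes == 2 else "multi:softprob",
            eval_metric="logloss", verbosity=0, **params,
        )
    raise InvalidFamilyError(f"unknown model family {family!r}")


class _LabelCodec:
    """String labels <-> integer codes (XGBoost wants integers)."""

    def __init__(self, labels: Sequence[str]):
        self.classes = tuple(sorted(set(labels)))
        self._pos = {c: i for i, c in enumerate(self.classes)}

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        return np.asarray([self._pos[l] for l in labels])

    def decode(self, codes: np.ndarray) -> list[str]:
        return [self.classes[int(c)] for c in codes]


def grid_search_fit(
    table: FeatureTable,
    family: str,
    grid: Mapping | None = None,
    inner_cv: int = 3,
    seed: int = 0,
):
    """Exhaustive grid search by inner-CV accuracy; refit on the full table.

    Ties are broken in favor of the earliest grid point.  Returns
    ``(fitted_model, best_params, codec)`` where ``codec`` maps the
    model's integer outputs back to class labels.
    """
    if family not in FAMILIES:
        raise InvalidFamilyError(f"unknown model family {family!r}")
    grid = dict(grid if grid is not None else DEFAULT_GRIDS[family])
    if not grid:
        raise InvalidArgumentError("empty hyper-parameter grid")
    codec = _LabelCodec(table.labels)
    y = codec.encode(table.labels)
    X = table.matrix

    points = list(ParameterGrid(grid))
    if len(points) == 1:
        best_params = points[0]
    else:
        skf = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        best_params, best_score = None, -np.inf
        for params in points:
            scores = []
            for tr, va in splits:
                model = _make_estimator(family, params, seed, len(codec.classes))
                model.fit(X[tr], y[tr])
                scores.append(float(np.mean(model.predict(X[va]) == y[va])))
            score = float(np.mean(scores))
            if score > best_score:        # strict > keeps first-in-grid on ties
                best_score, best_params = score, params
    model = _make_estimator(family, best_params, seed, len(codec.classes))
    model.fit(X, y)
    return model, dict(best_params), codec


def evaluate_loso(
    table: FeatureTable,
    family: str,
    grid: Mapping | None = None,
    inner_cv: int = 3,
    seed: int = 0,
    select_features: bool = False,
    select_kwargs: Mapping | None = None,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation with pooled confusion metrics.

    For each subject, feature selection (optional) and grid search run
    on all other subjects' segments only; predictions for the held-out
    subject's segments are pooled before computing metrics.
    """
    subjects = list(dict.fromkeys(table.subject_ids))   # stable order
    if len(subjects) < 3:
        raise InvalidArgumentError("LOSO needs at least 3 subjects")
    subj_arr = np.asarray(table.subject_ids)
    codec = _LabelCodec(table.labels)

    truths: list[str] = []
    preds: list[str] = []
    for s in subjects:
        test_idx = np.flatnonzero(subj_arr == s)
        train_idx = np.flatnonzero(subj_arr != s)
        if np.intersect1d(test_idx, train_idx).size:
            raise DataLeakError(f"subject {s} appears on both sides of the split")
        train = table.subset_rows(train_idx)
        test = table.subset_rows(test_idx)
        if select_features:
            sel = elastic_net_select(train, seed=seed, **(select_kwargs or {}))
            if sel.selected_names:
                train = train.select_columns(sel.selected_names)
                test = test.select_columns(sel.selected_names)
        model, _, fold_codec = grid_search_fit(train, family, grid, inner_cv, seed)
        preds.extend(fold_codec.decode(model.predict(test.matrix)))
        truths.extend(test.labels)

    confusion = ConfusionCounts.from_predictions(truths, preds, codec.classes)
    metrics = compute_metrics(confusion)
    return EvaluationReport(
        scheme="LOSO", per_class=metrics["per_class"], accuracy=metrics["accuracy"],
        confusion=confusion, model_family=family, best_params={}, seed=seed,
        truths=tuple(truths), predictions=tuple(preds),
        extras={"n_subjects": len(subjects)},
    )


def evaluate_leave_data_out(
    table: FeatureTable,
    family: str,
    grid: Mapping | None = None,
    ratio: float = 0.2,
    inner_cv: int = 3,
    seed: int = 0,
    stratified: bool = True,
    select_features: bool = False,
    select_kwargs: Mapping | None = None,
) -> EvaluationReport:
    """Stratified segment-level hold-out evaluation (subject overlap allowed)."""
    if not 0.0 < ratio < 1.0:
        raise InvalidArgumentError("ratio must be in (0, 1)")
    idx = np.arange(table.n_segments)
    labels = np.asarray(table.labels)
    train_idx, test_idx = train_test_split(
        idx, test_size=ratio, random_state=seed,
        stratify=labels if stratified else None,
    )
    if set(labels) - set(labels[train_idx]):
        raise DegenerateSplitError("a class is absent from the training split")
    train = table.subset_rows(train_idx)
    test = table.subset_rows(test_idx)
    if select_features:
        sel = elastic_net_select(train, seed=seed, **(select_kwargs or {}))
        if sel.selected_names:
            train = train.select_columns(sel.selected_names)
            test = test.select_columns(sel.selected_names)
    model, best_params, codec = grid_search_fit(train, family, grid, inner_cv, seed)
    preds = codec.decode(model.predict(test.matrix))
    confusion = ConfusionCounts.from_predictions(test.labels, preds, codec.classes)
    metrics = compute_metrics(confusion)
    return EvaluationReport(
        scheme="LEAVE_DATA_OUT", per_class=metrics["per_class"],
        accuracy=metrics["accuracy"], confusion=confusion, model_family=family,
        best_params=best_params, seed=seed,
        truths=tuple(test.labels), predictions=tuple(preds),
        extras={"ratio": ratio, "n_test": int(test_idx.size)},
    )
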