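"""Feature-based classification of images as problematic vs. okay for
deuteranopes, with the cross-validation and scoring protocol used to
evaluate such screens.

Training uses only the two definitive review labels; the "probably"
labels and grayscale images are excluded.  Class imbalance (problematic
images are the minority) is handled by inverse-frequency class weighting
for logistic regression and random forests.  Evaluation runs three
iterations of stratified five-fold cross-validation and summarizes AUROC
and AUPRC as the mean over iterations of the per-iteration median over
folds.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .metrics import METRIC_COLUMNS, MetricVector

__all__ = [
    "ReviewLabel",
    "LabeledExample",
    "CVPlan",
    "EvaluationResult",
    "CVSummary",
    "FeatureTransformer",
    "FittedModel",
    "FEATURE_COLUMNS",
    "ALGORITHMS",
    "impute_and_scale",
    "train_model",
    "cross_validate",
    "evaluate_predictions",
    "aggregate_article_labels",
    "examples_to_frame",
    "frame_to_examples",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
FEATURE_COLUMNS = METRIC_COLUMNS[:5]
ALGORITHMS = ("logistic_regression", "random_forest", "knn")
_ALGO_ALIASES = {"lr": "logistic_regression", "rf": "random_forest", "knn": "knn",
                 "logistic_regression": "logistic_regression",
                 "random_forest": "random_forest"}


class ReviewLabel(str, Enum):
    """Manual-review vocabulary for image accessibility."""

    DEFINITELY_PROBLEMATIC = "definitely_problematic"
    PROBABLY_PROBLEMATIC = "probably_problematic"
    PROBABLY_OKAY = "probably_okay"
    DEFINITELY_OKAY = "definitely_okay"
    GRAYSCALE = "grayscale"

    @property
    def is_definite(self) -> bool:
        return self in (ReviewLabel.DEFINITELY_PROBLEMATIC, ReviewLabel.DEFINITELY_OKAY)


@dataclass
class LabeledExample:
    features: MetricVector
    label: ReviewLabel
    source_id: str = ""


@dataclass
class EvaluationResult:
    """Confusion counts and scores for one model/test-set pairing.

    ``precision`` (and ``recall``) are NaN when their denominator is zero;
    ``auroc``/``auprc`` are NaN when the test labels contain one class.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    auroc: float
    auprc: float


@dataclass
class CVSummary:
    auroc: float                      # mean over iterations of per-iteration median
    auprc: float
    fold_results: list[tuple[int, int, EvaluationResult]]  # (iteration, fold, result)
    n_skipped_folds: int = 0


class FeatureTransformer:
    """Impute undefined spatial distances and standardize features.

    The spatial-distance metric is undefined (NaN) for images without
    high-ratio color pairs; such images are maximally unproblematic on
    that axis, so NaN is imputed with the training-set maximum plus one.
    Standardization (and the imputation value) use training-set statistics
    only, so test data never leaks into the transform.
    """

    def __init__(self) -> None:
        self.impute_value_: float | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureTransformer":
        X = np.asarray(X, dtype=np.float64)
        if X.size == 0:
            raise ValueError("cannot fit on an empty feature matrix")
        finite_spatial = X[:, 4][np.isfinite(X[:, 4])]
        self.impute_value_ = float(finite_spatial.max() + 1.0) if len(finite_spatial) else 1.0
        Xi = self._impute(X)
        self.mean_ = Xi.mean(axis=0)
        std = Xi.std(axis=0)
        self.std_ = np.where(std == 0.0, 1.0, std)
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        Xi = np.array(X, dtype=np.float64, copy=True)
        nan = ~np.isfinite(Xi[:, 4])
        Xi[nan, 4] = self.impute_value_
        return Xi

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("transformer is not fitted")
        return (self._impute(np.asarray(X, dtype=np.float64)) - self.mean_) / self.std_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def _feature_matrix(examples: Sequence[LabeledExample]) -> np.ndarray:
    return np.stack([ex.features.feature_array() for ex in examples])


def _label_array(examples: Sequence[LabeledExample]) -> np.ndarray:
    return np.array(
        [1 if ex.label is ReviewLabel.DEFINITELY_PROBLEMATIC else 0 for ex in examples]
    )


def impute_and_scale(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, FeatureTransformer]:
    """Fit a :class:`FeatureTransformer` on the examples and return the
    transformed matrix along with the fitted transformer."""
    if len(examples) == 0:
        raise ValueError("no examples given")
    t = FeatureTransformer()
    return t.fit_transform(_feature_matrix(examples)), t


def _make_estimator(algorithm: str, seed: int):
    algorithm = _ALGO_ALIASES.get(algorithm, algorithm)
    if algorithm == "logistic_regression":
        return LogisticRegression(solver="liblinear", class_weight="balanced",
                                  random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(class_weight="balanced", random_state=seed)
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class FittedModel:
    """A fitted transformer + estimator pair scoring the probability that
    an image is definitely problematic."""

    algorithm: str
    transformer: FeatureTransformer
    estimator: object

    def predict_scores(self, features: Sequence[MetricVector] | np.ndarray) -> np.ndarray:
        if len(features) and isinstance(features[0], MetricVector):
            X = np.stack([f.feature_array() for f in features])
        else:
            X = np.asarray(features, dtype=np.float64)
        Xs = self.transformer.transform(X)
        proba = self.estimator.predict_proba(Xs)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]


def _definite(examples: Sequence[LabeledExample]) -> list[LabeledExample]:
    return [ex for ex in examples if ex.label.is_definite]


def train_model(examples: Sequence[LabeledExample], algorithm: str = "logistic_regression",
                seed: int = 0) -> FittedModel:
    """Fit a binary classifier on the definitively labeled examples.

    Raises if fewer than two examples of either class are present.
    """
    kept = _definite(examples)
    y = _label_array(kept)
    if len(kept) < 4 or len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least two examples of each definite class")
    X = _feature_matrix(kept)
    t = FeatureTransformer().fit(X)
    est = _make_estimator(algorithm, seed)
    est.fit(t.transform(X), y)
    return FittedModel(_ALGO_ALIASES.get(algorithm, algorithm), t, est)


def evaluate_predictions(scores: Sequence[float], labels: Sequence[int],
                         cutoff: float = 0.5) -> EvaluationResult:
    """Confusion counts at the cutoff plus AUROC (trapezoidal) and AUPRC
    (precision-recall step integral)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n = len(labels)
    accuracy = (tp + tn) / n if n else math.nan
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    if len(np.unique(labels)) < 2:
        auroc = auprc = math.nan
    else:
        auroc = float(roc_auc_score(labels, scores))
        auprc = float(average_precision_score(labels, scores))
    return EvaluationResult(tp, fp, tn, fn, accuracy, precision, recall, auroc, auprc)


@dataclass
class CVPlan:
    """Repeated stratified k-fold assignments: ``n_iterations`` independent
    shuffles, each partitioning the examples into ``n_folds`` test folds."""

    n_iterations: int = 3
    n_folds: int = 5
    seed: int = 0

    def fold_assignments(self, labels: np.ndarray) -> list[np.ndarray]:
        """Per iteration, an array assigning each example a test-fold id."""
        out = []
        for it in range(self.n_iterations):
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                  random_state=self.seed + it)
            assign = np.empty(len(labels), dtype=np.int32)
            for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
                assign[test_idx] = fold
            out.append(assign)
        return out


def cross_validate(examples: Sequence[LabeledExample], algorithm: str = "logistic_regression",
                   plan: CVPlan | None = None) -> CVSummary:
    """Run the repeated stratified CV protocol and summarize AUROC/AUPRC
    as the mean over iterations of the per-iteration median over folds.

    Transform statistics (imputation value, standardization) are fit on
    each training split only.  Folds whose test split contains a single
    class are skipped with a warning.
    """
    plan = plan or CVPlan()
    kept = _definite(examples)
    y = _label_array(kept)
    X = _feature_matrix(kept)
    fold_results: list[tuple[int, int, EvaluationResult]] = []
    skipped = 0
    per_iter_auroc, per_iter_auprc = [], []
    for it, assign in enumerate(plan.fold_assignments(y)):
        aurocs, auprcs = [], []
        for fold in range(plan.n_folds):
            test = assign == fold
            train = ~test
            if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                skipped += 1
                msg = f"skipping degenerate fold {fold} of iteration {it} (single class)"
                logger.warning(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            t = FeatureTransformer().fit(X[train])
            est = _make_estimator(algorithm, plan.seed + it)
            est.fit(t.transform(X[train]), y[train])
            pos = list(est.classes_).index(1)
            scores = est.predict_proba(t.transform(X[test]))[:, pos]
            res = evaluate_predictions(scores, y[test])
            fold_results.append((it, fold, res))
            aurocs.append(res.auroc)
            auprcs.append(res.auprc)
        if aurocs:
            per_iter_auroc.append(float(np.median(aurocs)))
            per_iter_auprc.append(float(np.median(auprcs)))
    if not per_iter_auroc:
        raise ValueError("no valid folds; cannot summarize")
    return CVSummary(
        auroc=float(np.mean(per_iter_auroc)),
        auprc=float(np.mean(per_iter_auprc)),
        fold_results=fold_results,
        n_skipped_folds=skipped,
    )


def aggregate_article_labels(image_labels: Sequence[ReviewLabel]) -> ReviewLabel | None:
    """Collapse an article's image labels to an article-level label:
    problematic if any image is definitely problematic, else okay if any
    image is definitely okay, else no label (None)."""
    if len(image_labels) == 0:
        raise ValueError("empty label group")
    if ReviewLabel.DEFINITELY_PROBLEMATIC in image_labels:
        return ReviewLabel.DEFINITELY_PROBLEMATIC
    if ReviewLabel.DEFINITELY_OKAY in image_labels:
        return ReviewLabel.DEFINITELY_OKAY
    return None


def examples_to_frame(examples: Sequence[LabeledExample]) -> pd.DataFrame:
    rows = []
    for ex in examples:
        row = {"source_id": ex.source_id or ex.features.source_id,
               "label": ex.label.value}
        row.update({c: getattr(ex.features, c) for c in METRIC_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["source_id", "label", *METRIC_COLUMNS])


def frame_to_examples(df: pd.DataFrame) -> list[LabeledExample]:
    out = []
    for _, row in df.iterrows():
        mv = MetricVector(
            mean_pixelwise_dist=float(row["mean_pixelwise_dist"]),
            max_ratio=float(row["max_ratio"]),
            high_ratio_count=int(row["high_ratio_count"]),
            high_ratio_pixel_prop=float(row["high_ratio_pixel_prop"]),
            mean_spatial_dist=float(row["mean_spatial_dist"])
            if pd.notna(row["mean_spatial_dist"]) else math.nan,
            grayscale=bool(row["grayscale"]),
            source_id=str(row["source_id"]),
        )
        out.append(LabeledExample(mv, ReviewLabel(row["label"]), str(row["source_id"])))
    return out


def save_model(model: FittedModel, path: str | Path) -> Path:
    """Serialize a fitted model with a format-version tag."""
    path = Path(path)
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION, "algorithm": model.algorithm,
         "transformer": model.transformer, "estimator": model.estimator},
        path,
    )
    return path


def load_model(path: str | Path) -> FittedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version}")
    return FittedModel(payload["algorithm"], payload["transformer"], payload["estimator"])
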