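"""Leave-one-out cross-validation and classification metrics.

Each of the n samples is predicted by a model trained on the other n - 1,
so no predictor ever saw its held-out sample; feature selection,
imputation statistics and standardization are all recomputed inside each
fold from the training samples only.  Results aggregate into a confusion
matrix from which accuracy and (for binary tasks) the Matthews correlation
coefficient are derived:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention MCC = 0 when any denominator factor vanishes (an
uninformative classifier scores like a random one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import (
    MulticlassModel,
    SVMConfig,
    SVMModel,
    TreeModel,
    fit_binary,
    predict,
    predict_multiclass,
    train_decision_tree,
    train_multiclass,
)
from .data_model import (
    SamplePanel,
    build_feature_index,
    panel_feature_matrix,
    vectorize,
)
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """k x k counts, rows = true class, columns = predicted class.

    For binary use, ``positive`` names the class counted as positive; it
    defaults to the first label in sorted order.
    """

    labels: tuple[str, ...]
    counts: np.ndarray
    positive: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if c.shape != (k, k) or np.any(c < 0):
            raise ValidationError("confusion counts must be k x k nonnegative")
        self.counts = c
        if self.positive is None and k == 2:
            self.positive = self.labels[0]

    @classmethod
    def from_binary(
        cls, tp: int, fn: int, fp: int, tn: int, labels: tuple[str, str] = ("pos", "neg")
    ) -> "ConfusionMatrix":
        return cls(labels=labels, counts=np.array([[tp, fn], [fp, tn]]), positive=labels[0])

    @classmethod
    def from_predictions(
        cls,
        true: Sequence[str],
        predicted: Sequence[str],
        labels: Sequence[str] | None = None,
        positive: str | None = None,
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = sorted(set(true) | set(predicted))
        labels = tuple(labels)
        pos = {lab: k for k, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true, predicted):
            counts[pos[t], pos[p]] += 1
        return cls(labels=labels, counts=counts, positive=positive)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _binary_cells(self) -> tuple[int, int, int, int]:
        if len(self.labels) != 2:
            raise ValidationError("binary cells require a 2-class matrix")
        p = self.labels.index(self.positive)
        n = 1 - p
        tp = int(self.counts[p, p])
        fn = int(self.counts[p, n])
        fp = int(self.counts[n, p])
        tn = int(self.counts[n, n])
        return tp, tn, fp, fn

    @property
    def tp(self) -> int:
        return self._binary_cells()[0]

    @property
    def tn(self) -> int:
        return self._binary_cells()[1]

    @property
    def fp(self) -> int:
        return self._binary_cells()[2]

    @property
    def fn(self) -> int:
        return self._binary_cells()[3]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": self.counts.tolist(),
            "positive": self.positive,
        }


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples (trace / total)."""
    if cm.total == 0:
        raise DegenerateDataError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a binary confusion matrix;
    returns 0 when any denominator factor is zero."""
    tp, tn, fp, fn = cm._binary_cells()
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(den))


@dataclass
class FoldRecord:
    sample_id: str
    true_label: str
    predicted_label: str | None
    decision_value: float | None
    skipped: bool = False
    note: str = ""


@dataclass
class CVResult:
    records: list[FoldRecord]
    confusion: ConfusionMatrix
    accuracy: float
    mcc: float | None  # binary tasks only

    def to_dict(self) -> dict:
        return {
            "per_sample": [
                {
                    "sample_id": r.sample_id,
                    "true": r.true_label,
                    "predicted": r.predicted_label,
                    "decision_value": r.decision_value,
                    "skipped": r.skipped,
                    "note": r.note,
                }
                for r in self.records
            ],
            "confusion": self.confusion.to_dict(),
            "accuracy": self.accuracy,
            "mcc": self.mcc,
        }


class SVMTrainer:
    """Train/predict adapter for :func:`loocv`: binary SVM or one-vs-one
    ensemble depending on the number of classes in the fold."""

    def __init__(self, cfg: SVMConfig = SVMConfig()):
        self.cfg = cfg

    def fit(self, X: np.ndarray, labels: Sequence[str]):
        classes = sorted(set(labels))
        if len(classes) == 2:
            return fit_binary(X, labels, self.cfg)
        return train_multiclass(X, labels, self.cfg)

    def predict_one(self, model, x: np.ndarray) -> tuple[str, float | None]:
        if isinstance(model, SVMModel):
            lab, val = predict(model, x)
            return lab, val
        return predict_multiclass(model, x), None


class TreeTrainer:
    """Information-gain decision-tree adapter for :func:`loocv`."""

    def __init__(self, min_leaf: int = 1):
        self.min_leaf = min_leaf

    def fit(self, X: np.ndarray, labels: Sequence[str]) -> TreeModel:
        return train_decision_tree(X, labels, self.min_leaf)

    def predict_one(self, model: TreeModel, x: np.ndarray) -> tuple[str, None]:
        return model.predict_one(x), None


def loocv(
    panel: SamplePanel,
    label_field: str,
    trainer=None,
    missing_policy: str = "intersect",
) -> CVResult:
    """Leave-one-out cross-validation over a labelled panel.

    For every sample, a model is trained on the remaining samples and asked
    to predict the held-out one.  The feature index, any imputation means
    and the standardization statistics come from the training fold alone.
    Folds whose training set collapses to a single class are recorded as
    skipped with a warning rather than aborting the run.
    """
    if trainer is None:
        trainer = SVMTrainer()
    labels = panel.labels(label_field)
    if len(set(labels)) < 2:
        raise DegenerateDataError("panel carries a single class")
    records: list[FoldRecord] = []
    for hold in range(len(panel)):
        train_samples = [s for k, s in enumerate(panel) if k != hold]
        test_sample = panel.samples[hold]
        train_panel = SamplePanel(train_samples, panel.fragment_map)
        train_labels = [s.label(label_field) for s in train_samples]
        if len(set(train_labels)) < 2:
            logger.warning(
                "fold %s: training set has a single class; fold skipped",
                test_sample.sample_id,
            )
            records.append(
                FoldRecord(
                    sample_id=test_sample.sample_id,
                    true_label=test_sample.label(label_field),
                    predicted_label=None,
                    decision_value=None,
                    skipped=True,
                    note="single-class training fold",
                )
            )
            continue
        idx = build_feature_index(train_panel, missing_policy=missing_policy)
        Xdf = panel_feature_matrix(train_panel, idx, missing_policy=missing_policy)
        X = Xdf.to_numpy()
        impute = X.mean(axis=0) if missing_policy == "impute_row_mean" else None
        vec = vectorize(
            test_sample.matrix,
            idx,
            missing_policy=missing_policy,
            impute_values=impute,
            sample_id=test_sample.sample_id,
        )
        model = trainer.fit(X, train_labels)
        pred, val = trainer.predict_one(model, vec.values)
        records.append(
            FoldRecord(
                sample_id=test_sample.sample_id,
                true_label=test_sample.label(label_field),
                predicted_label=pred,
                decision_value=val,
            )
        )
    evaluated = [r for r in records if not r.skipped]
    if not evaluated:
        raise DegenerateDataError("every fold was degenerate")
    classes = tuple(sorted(set(labels)))
    cm = ConfusionMatrix.from_predictions(
        [r.true_label for r in evaluated],
        [r.predicted_label for r in evaluated],
        labels=classes,
    )
    return CVResult(
        records=records,
        confusion=cm,
        accuracy=accuracy(cm),
        mcc=mcc(cm) if len(classes) == 2 else None,
    )
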