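"""Model evaluation: five-class accuracy, grouped cross-validation, timing.

Models trained on either averaging scheme are always scored against both
validation sets derived from the same held-out samples: validation set 1
holds the four-direction mean spectra (one per sample) and validation set 2
the per-direction means (four per sample).  Cross-validation folds are
grouped by sample so that no physical sample contributes spectra to both
sides of a fold, and prediction wall-time of the classifier head is
reported separately from CNN feature extraction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedGroupKFold


def accuracy(predicted, truth) -> float:
    """Fraction of matching labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    if predicted.shape != truth.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(predicted == truth))


def confusion(predicted, truth, n_classes: int = 5) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted."""
    return _sk_confusion(truth, predicted, labels=np.arange(n_classes))


@dataclass
class EvaluationReport:
    """Scores of one trained pipeline on every dataset of the protocol."""

    scheme: str
    kernel_size: int
    head: str
    calibration_accuracy: float
    validation1_accuracy: float
    validation2_accuracy: float
    cross_validation_accuracy: float | None = None
    cv_fold_accuracies: tuple[float, ...] = ()
    confusion_validation2: np.ndarray | None = None
    head_predict_seconds: float = float("nan")
    feature_extract_seconds: float = float("nan")

    def as_row(self) -> dict:
        return {
            "model": f"CNN-{self.head.capitalize() if self.head != 'svm' else 'SVM'}"
                     if self.head != "elm" else "CNN-ELM",
            "scheme": self.scheme,
            "kernel": self.kernel_size,
            "cal_acc": self.calibration_accuracy,
            "cv_acc": self.cross_validation_accuracy,
            "val1_acc": self.validation1_accuracy,
            "val2_acc": self.validation2_accuracy,
            "predict_s": self.head_predict_seconds,
        }


def timed_predict(bundle, matrices: np.ndarray):
    """Predict labels while timing the head separately from the CNN.

    ``bundle`` must expose ``extract_features(matrices)`` and
    ``predict_head(features)``.  Returns ``(labels, head_seconds,
    feature_seconds)``; timing never alters the labels.
    """
    t0 = time.perf_counter()
    feats = bundle.extract_features(matrices)
    t1 = time.perf_counter()
    labels = bundle.predict_head(feats)
    t2 = time.perf_counter()
    return labels, t2 - t1, t1 - t0


def cross_validate(fit_predict, matrices: np.ndarray, labels: np.ndarray,
                   sample_ids, k: int = 5, seed: int = 0):
    """Grouped, stratified k-fold cross-validation of a full pipeline.

    ``fit_predict(train_matrices, train_labels, test_matrices)`` must train
    a fresh pipeline and return predicted labels for the test matrices.
    All spectra of one sample share a fold (no sample-level leakage).
    Returns ``(mean_accuracy, per_fold_accuracies)``.
    """
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    for train_idx, test_idx in cv.split(matrices, labels, groups=sample_ids):
        if len(np.unique(labels[train_idx])) < len(np.unique(labels)):
            import warnings
            warnings.warn("a training fold is missing classes", stacklevel=2)
        assert not set(sample_ids[train_idx]) & set(sample_ids[test_idx])
        pred = fit_predict(matrices[train_idx], labels[train_idx],
                           matrices[test_idx])
        fold_acc.append(accuracy(pred, labels[test_idx]))
    return float(np.mean(fold_acc)), tuple(fold_acc)


def audit_no_leakage(train_ids, eval_ids) -> None:
    """Raise if any sample contributes spectra to both sides."""
    shared = set(np.asarray(train_ids)) & set(np.asarray(eval_ids))
    if shared:
        raise RuntimeError(f"sample leakage between training and evaluation: "
                           f"{sorted(shared)[:5]}")


def compare_models(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Tabulate reports, best models first.

    Sorted by validation-set-2 accuracy then validation-set-1 accuracy
    (stable, so equal rows keep their original order).  When both averaging
    schemes are present, a ``max_scheme_difference`` column reports, per
    head, the largest accuracy gap between schemes over the shared
    validation sets.
    """
    if not reports:
        raise ValueError("no reports to compare")
    df = pd.DataFrame([r.as_row() for r in reports])
    df = df.sort_values(["val2_acc", "val1_acc"], ascending=False,
                        kind="stable").reset_index(drop=True)
    diffs = {}
    for head in {r.head for r in reports}:
        by_scheme = {}
        for r in reports:
            if r.head == head:
                by_scheme.setdefault(r.scheme, []).append(
                    (r.validation1_accuracy, r.validation2_accuracy))
        if len(by_scheme) == 2:
            (a1, a2), (b1, b2) = (np.max(v, axis=0) for v in by_scheme.values())
            diffs[head] = float(max(abs(a1 - b1), abs(a2 - b2)))
        elif len(by_scheme) == 1:
            diffs[head] = 0.0
    df.attrs["max_scheme_difference"] = diffs
    return df
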