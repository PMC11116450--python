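"""Youden-index binarization of ordinal clinical descriptors.

Each descriptor is collected on a discrete non-binary scale (WOMAC
subscales, HAD, the Pain Catastrophizing Scale, echographic grades).  To
serve as a classification target it is cut into two groups at the
threshold, found by grid search over midpoints between consecutive
observed values, that maximizes Youden's index

    J = TP/(TP+FN) + TN/(TN+FP) - 1 = sensitivity + specificity - 1,

where the confusion counts come from the pooled held-out predictions of a
nested leave-one-out linear-SVM run at that candidate threshold.  A
descriptor is retained as a target only if the mean train-set accuracy
across LOO folds reaches 0.75; below that the descriptor is considered not
properly binarizable and is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .svm import SvmConfig, nested_loo

__all__ = [
    "ConfusionCounts",
    "BinarizationResult",
    "UndefinedIndexError",
    "NoCandidatesError",
    "NoValidThresholdError",
    "youden_index",
    "candidate_thresholds",
    "binarize",
    "select_threshold",
    "binarize_cohort",
    "write_thresholds",
    "read_thresholds",
    "RETENTION_GATE",
]

#: Minimum mean train-set accuracy for a descriptor to be retained.
RETENTION_GATE = 0.75


class UndefinedIndexError(ValueError):
    """Youden's index is undefined when either class is empty."""


class NoCandidatesError(ValueError):
    """A constant descriptor offers no candidate thresholds."""


class NoValidThresholdError(ValueError):
    """Every candidate threshold was skipped."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class BinarizationResult:
    descriptor: str
    threshold: float
    youden: float
    fold_train_accuracies: list
    mean_train_accuracy: float
    retained: bool
    candidates: list          # every evaluated (threshold, J, mean train acc)
    skipped: list             # candidates skipped for degenerate class sizes


def youden_index(counts: ConfusionCounts) -> float:
    """J = sensitivity + specificity - 1, in [-1, 1]."""
    if counts.TP + counts.FN == 0 or counts.TN + counts.FP == 0:
        raise UndefinedIndexError("empty class: Youden's index undefined")
    sens = counts.TP / (counts.TP + counts.FN)
    spec = counts.TN / (counts.TN + counts.FP)
    return sens + spec - 1.0


def candidate_thresholds(values) -> np.ndarray:
    """Ascending midpoints between consecutive distinct observed values."""
    distinct = np.unique(np.asarray(values, dtype=float))
    distinct = distinct[~np.isnan(distinct)]
    if len(distinct) < 2:
        raise NoCandidatesError("constant descriptor: no candidate thresholds")
    return (distinct[:-1] + distinct[1:]) / 2


def binarize(values, threshold: float):
    """Label 1 iff value > threshold ("worse symptoms"); NaN stays NaN."""
    arr = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    out = (arr > threshold).astype(float)
    out[arr.isna()] = np.nan
    return out


def _pooled_confusion(folds) -> ConfusionCounts:
    pred = np.array([f.decision_value > 0 for f in folds], dtype=int)
    true = np.array([f.y_true for f in folds], dtype=int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (true == 1)).sum()),
        FN=int(((pred == 0) & (true == 1)).sum()),
        TN=int(((pred == 0) & (true == 0)).sum()),
        FP=int(((pred == 1) & (true == 0)).sum()),
    )


def select_threshold(features, descriptor, classifier_cfg: SvmConfig | None = None,
                     name: str = "descriptor") -> BinarizationResult:
    """Grid search the binarization threshold maximizing Youden's J.

    For each candidate (midpoints of the observed descriptor values) the
    descriptor is binarized and a nested-LOO linear SVM predicts the label
    from ``features``; J is computed on the pooled held-out predictions and
    the mean train accuracy across folds feeds the 0.75 retention gate.
    Candidates leaving either class with < 2 members are skipped (LOO
    training folds would be degenerate).  Ties in J resolve to the smallest
    threshold.
    """
    cfg = classifier_cfg or SvmConfig(c_grid=(1.0,))
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    desc = np.asarray(descriptor, dtype=float)
    if len(desc) != len(X):
        raise ValueError("features and descriptor lengths differ")

    cands = candidate_thresholds(desc)
    evaluated, skipped = [], []
    best = None
    for t in cands:
        y = (desc > t).astype(int)
        n1 = int(y.sum())
        if min(n1, len(y) - n1) < 2:
            skipped.append(float(t))
            continue
        folds, _ = nested_loo(X, y, cfg)
        try:
            J = youden_index(_pooled_confusion(folds))
        except UndefinedIndexError:
            # paper_compat can exclude the last subject's class from the pool
            skipped.append(float(t))
            continue
        accs = [f.train_accuracy for f in folds]
        mean_acc = float(np.mean(accs))
        evaluated.append((float(t), float(J), mean_acc, accs))
        if best is None or J > evaluated[best][1]:
            best = len(evaluated) - 1
    if best is None:
        raise NoValidThresholdError(f"{name}: all candidate thresholds skipped")
    t, J, mean_acc, accs = evaluated[best]
    return BinarizationResult(
        descriptor=name,
        threshold=t,
        youden=J,
        fold_train_accuracies=accs,
        mean_train_accuracy=mean_acc,
        retained=mean_acc >= RETENTION_GATE,
        candidates=[(c[0], c[1], c[2]) for c in evaluated],
        skipped=skipped,
    )


def binarize_cohort(cohort, classifier_cfg: SvmConfig | None = None,
                    descriptors=None) -> dict:
    """Select a threshold for every descriptor, using the remaining
    descriptors (continuous form) as the grid search's feature set.

    Returns ``{descriptor: BinarizationResult}``.
    """
    clinical = cohort.columns_of_kind("clinical")
    results = {}
    for target in (descriptors or clinical):
        others = [c for c in clinical if c != target]
        sub = cohort.data[others + [target]].dropna()
        results[target] = select_threshold(
            sub[others].to_numpy(), sub[target].to_numpy(), classifier_cfg, name=target)
    return results


def write_thresholds(results: dict, path) -> None:
    payload = {
        name: {
            "threshold": float(r.threshold),
            "youden": float(r.youden),
            "mean_train_accuracy": float(r.mean_train_accuracy),
            "retained": bool(r.retained),
        }
        for name, r in results.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_thresholds(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
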