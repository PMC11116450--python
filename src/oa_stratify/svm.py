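"""Nested leave-one-out linear-SVM classification.

The classifier is the soft-margin linear SVM minimizing
``(1/2) w^T w + C * sum(zeta_n)`` subject to ``y_n (w^T x_n + b) >= 1 -
zeta_n``.  Each outer leave-one-out fold z-scores features on its training
remainder, tunes the penalty C by inner stratified k-fold cross-validation
(k = 5), fits, and records the fold's weight vector and the held-out
decision value.  Feature importances are the fold-averaged weights,
absolute value, min-max mapped to [0, 1]; performance is the Mann-Whitney
AUC over the pooled held-out decision values.

Two outer fold modes are provided.  ``"standard"`` is ordinary LOO (N
folds).  ``"paper_compat"`` holds out only subjects 1..N-1 (N-1 folds), so
a 51-subject task trains 50 models and a 25-subject task trains 24, and the
fold-averaged weight divides by N-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

__all__ = [
    "SvmConfig",
    "FoldResult",
    "ClassifierReport",
    "DegenerateLabelsError",
    "fit_linear_svm",
    "tune_C",
    "nested_loo",
    "importance",
    "pooled_auc",
    "run_task",
    "run_all_tasks",
    "importance_matrix",
]

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-3, 4))


class DegenerateLabelsError(ValueError):
    """Labels contain a single class where both are required."""


@dataclass(frozen=True)
class SvmConfig:
    """Configuration of one nested-LOO classification task.

    ``c_grid`` is the inner-CV search grid for the penalty C (a single
    value skips inner tuning); ``backend`` selects the solver —
    ``"libsvm"`` (sklearn SVC, exact hinge dual, fine for cohort-sized
    problems) or ``"liblinear"`` (LinearSVC with hinge loss, much faster
    for thousands of samples).
    """

    c_grid: tuple = DEFAULT_C_GRID
    inner_k: int = 5
    fold_mode: str = "paper_compat"
    seed: int = 0
    backend: str = "libsvm"
    standardize: bool = True

    def __post_init__(self):
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValueError("C grid must be non-empty and strictly positive")
        if self.inner_k < 2:
            raise ValueError("inner_k must be >= 2")
        if self.fold_mode not in ("paper_compat", "standard"):
            raise ValueError(f"unknown fold mode {self.fold_mode!r}")
        if self.backend not in ("libsvm", "liblinear"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class FoldResult:
    held_out_id: object
    weights: np.ndarray
    intercept: float
    selected_C: float
    decision_value: float
    y_true: int
    train_accuracy: float


@dataclass
class ClassifierReport:
    task_id: str
    feature_names: list
    fold_results: list
    mean_weights: np.ndarray
    importances: np.ndarray
    auc: float
    mean_train_accuracy: float
    threshold: float | None = None
    all_zero_weights: bool = False
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "feature_names": list(self.feature_names),
            "n_folds": len(self.fold_results),
            "selected_C": [f.selected_C for f in self.fold_results],
            "mean_weights": self.mean_weights.tolist(),
            "importances": self.importances.tolist(),
            "auc": float(self.auc),
            "mean_train_accuracy": float(self.mean_train_accuracy),
            "threshold": self.threshold,
            "all_zero_weights": self.all_zero_weights,
            "warnings": list(self.warnings),
        }


def _standardize(train: np.ndarray, other: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    if other is None:
        return (train - mu) / sd
    return (train - mu) / sd, (other - mu) / sd


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float, backend: str = "libsvm"):
    """Fit the soft-margin linear SVM; returns (weights, intercept, model)."""
    if backend == "libsvm":
        model = SVC(kernel="linear", C=C)
    else:
        model = LinearSVC(loss="hinge", C=C, max_iter=1_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter on noise labels
        model.fit(X, y)
    return model.coef_[0].copy(), float(model.intercept_[0]), model


def tune_C(train_features: np.ndarray, train_labels: np.ndarray, cfg: SvmConfig) -> float:
    """Inner k-fold grid search for C; ties broken toward the smallest C."""
    y = np.asarray(train_labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateLabelsError("single-class training labels")
    if len(cfg.c_grid) == 1:
        return float(cfg.c_grid[0])
    k = min(cfg.inner_k, int(counts.min()))
    if k < 2:
        # too few minority members for CV: fall back to the smallest C
        return float(min(cfg.c_grid))
    X = np.asarray(train_features, dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))
    best_C, best_acc = None, -np.inf
    for C in sorted(cfg.c_grid):
        accs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2:
                continue
            if cfg.standardize:
                Xtr, Xte = _standardize(X[tr], X[te])
            else:
                Xtr, Xte = X[tr], X[te]
            _, _, model = fit_linear_svm(Xtr, y[tr], C, cfg.backend)
            accs.append(float((model.predict(Xte) == y[te]).mean()))
        acc = float(np.mean(accs)) if accs else -np.inf
        if acc > best_acc:  # strict: earlier (smaller) C wins ties
            best_acc, best_C = acc, C
    return float(best_C)


def nested_loo(features, labels, cfg: SvmConfig = SvmConfig(), subject_ids=None):
    """Outer leave-one-out loop; returns (list of FoldResult, warnings).

    ``paper_compat`` mode holds out subjects 1..N-1 (N-1 folds); ``standard``
    holds out every subject (N folds).  Folds whose training remainder is
    single-class are skipped with a recorded warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(y)
    if subject_ids is None:
        subject_ids = list(range(n))
    if n < 5:
        raise ValueError("need at least 5 samples for nested LOO")
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise DegenerateLabelsError("both classes need >= 2 members")

    held_out = range(n - 1) if cfg.fold_mode == "paper_compat" else range(n)
    results, warn = [], []
    for i in held_out:
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            warn.append(f"fold {subject_ids[i]}: single-class training set, skipped")
            continue
        if cfg.standardize:
            Xtr, Xte = _standardize(X[mask], X[~mask])
        else:
            Xtr, Xte = X[mask], X[~mask]
        C = tune_C(Xtr, ytr, cfg)
        w, b, model = fit_linear_svm(Xtr, ytr, C, cfg.backend)
        results.append(FoldResult(
            held_out_id=subject_ids[i],
            weights=w,
            intercept=b,
            selected_C=C,
            decision_value=float(model.decision_function(Xte)[0]),
            y_true=int(y[i]),
            train_accuracy=float((model.predict(Xtr) == ytr).mean()),
        ))
    return results, warn


def importance(fold_results) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fold-averaged weights -> normalized importances in [0, 1].

    Returns (importances, mean_weights, all_zero_flag).  The mean weight
    per feature is taken across folds, then |mean| is min-max mapped to
    [0, 1]; if all |mean| are equal and nonzero every feature maps to 1,
    and all-zero weights map to all-zero importances (flagged).
    """
    if not fold_results:
        raise ValueError("no folds")
    W = np.vstack([f.weights for f in fold_results])
    mean_w = W.mean(axis=0)
    a = np.abs(mean_w)
    if np.all(a == 0):
        return np.zeros_like(a), mean_w, True
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.ones_like(a), mean_w, False
    return (a - lo) / (hi - lo), mean_w, False


def pooled_auc(fold_results) -> float:
    """Mann-Whitney AUC over pooled held-out decision values; ties count 1/2."""
    scores = np.array([f.decision_value for f in fold_results], dtype=float)
    y = np.array([f.y_true for f in fold_results], dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise DegenerateLabelsError("pooled held-out labels are single-class")
    ranks = rankdata(scores)  # midranks give the half-credit tie convention
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


# ---------------------------------------------------------------------------
# task assembly


def _threshold_of(entry) -> float:
    """Accept a raw number, a thresholds-file dict, or a BinarizationResult."""
    if isinstance(entry, dict):
        return float(entry["threshold"])
    if hasattr(entry, "threshold"):
        return float(entry.threshold)
    return float(entry)


def _retained_of(entry) -> bool:
    if isinstance(entry, dict):
        return bool(entry.get("retained", True))
    if hasattr(entry, "retained"):
        return bool(entry.retained)
    return True


def _clinical_features(cohort, target: str, prune_cutoff: float = 0.7):
    """Remaining descriptors after the vs-target Pearson prune, target excluded."""
    from .features import prune_vs_target

    clinical = cohort.columns_of_kind("clinical")
    others = [c for c in clinical if c != target]
    report = prune_vs_target(cohort.data[others], cohort.data[target], cutoff=prune_cutoff)
    return report.kept, report


def run_task(cohort, target: str, input_set: str, thresholds: dict,
             cfg: SvmConfig = SvmConfig(), tf_table: pd.DataFrame | None = None) -> ClassifierReport:
    """One classification task: a binarized descriptor vs one input-feature set.

    ``input_set`` is ``clinical`` (remaining descriptors after the
    vs-target Pearson prune, all subjects), ``sf`` (the analyte panel,
    synovial-fluid subset only) or ``tf`` (simulated transcription-factor
    activations, same subset).  The target column never enters its own
    feature set.
    """
    from .binarization import binarize

    if target not in thresholds:
        raise KeyError(f"no binarization threshold for {target!r}")
    thr = _threshold_of(thresholds[target])
    warn = []
    if input_set == "clinical":
        feats, _ = _clinical_features(cohort, target)
        table = cohort.data[feats].dropna()
    elif input_set == "sf":
        feats = cohort.columns_of_kind("analyte")
        table = cohort.data[feats].dropna()
    elif input_set == "tf":
        if tf_table is None:
            raise ValueError("tf input set requires a TF activation table")
        feats = list(tf_table.columns)
        table = tf_table.dropna()
    else:
        raise ValueError(f"unknown input set {input_set!r}")
    if target in feats:
        raise ValueError("target leaked into its own feature set")

    y = binarize(cohort.data.loc[table.index, target], thr)
    keep = ~y.isna()
    table, y = table[keep], y[keep].astype(int)
    folds, w = nested_loo(table.to_numpy(), y.to_numpy(), cfg, subject_ids=list(table.index))
    warn.extend(w)
    imps, mean_w, zero = importance(folds)
    return ClassifierReport(
        task_id=f"{target}/{input_set}",
        feature_names=feats,
        fold_results=folds,
        mean_weights=mean_w,
        importances=imps,
        auc=pooled_auc(folds),
        mean_train_accuracy=float(np.mean([f.train_accuracy for f in folds])),
        threshold=thr,
        all_zero_weights=zero,
        warnings=warn,
    )


def run_all_tasks(cohort, thresholds: dict, tf_table: pd.DataFrame | None,
                  cfg: SvmConfig = SvmConfig(), input_sets=("clinical", "sf", "tf")) -> list:
    """All retained-descriptor x input-set tasks (7 x 3 = 21 by default)."""
    retained = [d for d, res in thresholds.items() if _retained_of(res)]
    reports = []
    for target in retained:
        for input_set in input_sets:
            if input_set == "tf" and tf_table is None:
                continue
            reports.append(run_task(cohort, target, input_set, thresholds, cfg, tf_table))
    return reports


def importance_matrix(reports, input_set: str) -> pd.DataFrame:
    """Targets x features matrix of normalized importances.

    Features omitted from a task (e.g. pruned, or the target itself in the
    clinical set) appear as NaN — the blank cells of the importance heatmaps.
    """
    rows = [r for r in reports if r.task_id.endswith(f"/{input_set}")]
    if not rows:
        raise ValueError(f"no reports for input set {input_set!r}")
    all_feats: list = []
    for r in rows:
        for f in r.feature_names:
            if f not in all_feats:
                all_feats.append(f)
    targets = [r.task_id.split("/")[0] for r in rows]
    if input_set == "clinical":
        for t in targets:
            if t not in all_feats:
                all_feats.append(t)
    mat = pd.DataFrame(np.nan, index=targets, columns=all_feats)
    for r, t in zip(rows, targets):
        mat.loc[t, list(r.feature_names)] = r.importances
    return mat
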