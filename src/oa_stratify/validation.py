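"""Transfer of cohort-derived binarization thresholds to an external
OAI-like table.

Protocol, in fixed order: (1) exclude rows flagged for knee-surgery
history, (2) drop rows with less than 80% of variables completed, (3)
greedy pairwise Pearson pruning at |r| > 0.7, (4) information-gain top-50
feature ranking per target, (5) a C-tuned linear SVM evaluated by
stratified 5-fold cross-validation accuracy for each of the six
WOMAC-style targets (left/right pain, functionality, rigidity), binarized
at the transferred thresholds.  The accuracy scheme is recorded in the
report, since a single train-set accuracy would be optimistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import EXTERNAL_TARGETS, CohortTable
from .features import (EmptyTableError, completeness_filter, prune_pairwise,
                       rank_by_information_gain)
from .svm import SvmConfig, _standardize, _threshold_of, fit_linear_svm, tune_C

__all__ = [
    "ValidationProtocolConfig",
    "ValidationReport",
    "ScaleMismatchError",
    "apply_exclusions",
    "apply_thresholds",
    "validate",
]

#: cohort descriptor whose threshold transfers to each external target
TARGET_SOURCES = {
    "WOMAC_pain_L": "JP", "WOMAC_pain_R": "JP",
    "WOMAC_function_L": "FU", "WOMAC_function_R": "FU",
    "WOMAC_rigidity_L": "RI", "WOMAC_rigidity_R": "RI",
}


class ScaleMismatchError(ValueError):
    """External target scale differs from the threshold's declared scale."""


@dataclass(frozen=True)
class ValidationProtocolConfig:
    surgery_flags: tuple = ("surgery_history",)
    completeness_min: float = 0.8
    pairwise_cutoff: float = 0.7
    ig_top_k: int = 50
    svm: SvmConfig = SvmConfig(backend="liblinear", fold_mode="standard")
    eval_folds: int = 5
    seed: int = 0
    targets: tuple = EXTERNAL_TARGETS

    def __post_init__(self):
        if self.eval_folds < 2:
            raise ValueError("eval_folds must be >= 2")


@dataclass
class ValidationReport:
    per_target_accuracy: dict
    mean_accuracy: float
    n_input: int
    n_after_flags: int
    n_after_completeness: int
    features_after_pruning: int
    selected_features: dict       # target -> top-k feature list
    class_balance: dict           # target -> positive fraction
    skipped_targets: list
    scheme: str = "stratified 5-fold CV accuracy"
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "scheme": self.scheme,
                "per_target_accuracy": {k: float(v) for k, v in self.per_target_accuracy.items()},
                "mean_accuracy": float(self.mean_accuracy),
                "n_input": self.n_input,
                "n_after_flags": self.n_after_flags,
                "n_after_completeness": self.n_after_completeness,
                "features_after_pruning": self.features_after_pruning,
                "selected_features": {k: list(v) for k, v in self.selected_features.items()},
                "class_balance": {k: float(v) for k, v in self.class_balance.items()},
                "skipped_targets": list(self.skipped_targets),
                "warnings": list(self.warnings),
            }, fh, indent=2)

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"accuracy": pd.Series(self.per_target_accuracy)})
        df.index.name = "classifier"
        return df


def apply_exclusions(table: CohortTable, cfg: ValidationProtocolConfig):
    """Remove surgery-flagged rows, then rows under the completeness minimum.

    Returns (filtered table, counts dict)."""
    df = table.data
    for col in cfg.surgery_flags:
        if col not in df.columns:
            raise KeyError(f"flag column {col!r} missing")
    flagged = df[list(cfg.surgery_flags)].fillna(0).astype(bool).any(axis=1)
    kept = CohortTable(df[~flagged], dict(table.kinds), dict(table.ordinal_ranges))
    n_flagged = int(flagged.sum())
    filtered = completeness_filter(kept, cfg.completeness_min)
    counts = {
        "input": len(df),
        "flagged": n_flagged,
        "incomplete": len(kept.data) - len(filtered.data),
        "remaining": len(filtered.data),
    }
    return filtered, counts


def apply_thresholds(table: CohortTable, thresholds: dict,
                     target_sources: dict = TARGET_SOURCES) -> pd.DataFrame:
    """Binarize each external target at its transferred cohort threshold.

    The external target must be on the same scale as the source
    descriptor; if the table declares an ordinal range whose span cannot
    contain the threshold, a ScaleMismatchError is raised rather than any
    silent rescale.
    """
    from .binarization import binarize

    out = {}
    for target, source in target_sources.items():
        if target not in table.data.columns:
            raise KeyError(f"target column {target!r} missing from table")
        if source not in thresholds:
            raise KeyError(f"no cohort threshold for source descriptor {source!r}")
        thr = _threshold_of(thresholds[source])
        if target in table.ordinal_ranges:
            lo, hi = table.ordinal_ranges[target]
            if not (lo < thr < hi):
                raise ScaleMismatchError(
                    f"threshold {thr} outside declared range [{lo}, {hi}] of {target!r}")
        out[target] = binarize(table.data[target], thr)
    return pd.DataFrame(out, index=table.data.index)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, cfg: ValidationProtocolConfig) -> float:
    skf = StratifiedKFold(n_splits=cfg.eval_folds, shuffle=True, random_state=cfg.seed)
    accs = []
    for tr, te in skf.split(X, y):
        Xtr, Xte = _standardize(X[tr], X[te])
        C = tune_C(Xtr, y[tr], cfg.svm)
        _, _, model = fit_linear_svm(Xtr, y[tr], C, cfg.svm.backend)
        accs.append(float((model.predict(Xte) == y[te]).mean()))
    return float(np.mean(accs))


def validate(table: CohortTable, thresholds: dict,
             cfg: ValidationProtocolConfig = ValidationProtocolConfig()) -> ValidationReport:
    """Full external-validation protocol; returns per-target and mean accuracy."""
    warns = []
    filtered, counts = apply_exclusions(table, cfg)
    if not len(filtered.data):
        raise EmptyTableError("exclusions removed every row")

    feature_cols = [c for c in filtered.data.columns
                    if c not in cfg.targets and c not in cfg.surgery_flags]
    feats = filtered.data[feature_cols]
    pruned = prune_pairwise(feats, cfg.pairwise_cutoff)
    if not pruned.kept:
        raise EmptyTableError("pairwise pruning removed every feature")
    if len(pruned.kept) < cfg.ig_top_k:
        warns.append(f"only {len(pruned.kept)} features survive pruning "
                     f"(top-{cfg.ig_top_k} requested)")

    labels = apply_thresholds(filtered, thresholds,
                              {t: TARGET_SOURCES[t] for t in cfg.targets})
    accuracies, selected, balance, skipped = {}, {}, {}, []
    for target in cfg.targets:
        y = labels[target]
        ok = ~y.isna()
        yv = y[ok].astype(int).to_numpy()
        if len(np.unique(yv)) < 2 or np.bincount(yv).min() < cfg.eval_folds:
            skipped.append(target)
            warns.append(f"{target}: single-class or too-small class after binarization, skipped")
            continue
        balance[target] = float(yv.mean())
        sub = feats.loc[ok, pruned.kept]
        # impute remaining missing cells at the column median before ranking/fitting
        sub = sub.fillna(sub.median())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top = rank_by_information_gain(sub, yv, k=cfg.ig_top_k)
        selected[target] = top
        accuracies[target] = _cv_accuracy(sub[top].to_numpy(), yv, cfg)
    if not accuracies:
        raise EmptyTableError("every target skipped after binarization")

    return ValidationReport(
        per_target_accuracy=accuracies,
        mean_accuracy=float(np.mean(list(accuracies.values()))),
        n_input=counts["input"],
        n_after_flags=counts["input"] - counts["flagged"],
        n_after_completeness=counts["remaining"],
        features_after_pruning=len(pruned.kept),
        selected_features=selected,
        class_balance=balance,
        skipped_targets=skipped,
        scheme=f"stratified {cfg.eval_folds}-fold CV accuracy (seed {cfg.seed})",
        warnings=warns,
    )
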