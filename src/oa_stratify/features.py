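"""Pearson-correlation pruning, information-gain ranking, completeness filtering.

Two pruning rules are used at different stages of the pipeline: the cohort
stage drops input features whose |Pearson r| with the targeted output
exceeds 0.7 (redundancy with the target), while the external-validation
stage greedily removes features with |r| > 0.7 against any already-kept
feature (pairwise redundancy).  Information gain — the reduction in label
entropy after conditioning on a discretized feature, in bits — ranks the
surviving features; rows with less than 80% of variables completed are
excluded beforehand.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionReport",
    "UndefinedCorrelationError",
    "ZeroEntropyError",
    "EmptyTableError",
    "pearson_r",
    "prune_vs_target",
    "prune_pairwise",
    "information_gain",
    "rank_by_information_gain",
    "completeness_filter",
]


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined for constant or too-short vectors."""


class ZeroEntropyError(ValueError):
    """Single-class labels carry no entropy to reduce."""


class EmptyTableError(ValueError):
    pass


@dataclass
class SelectionReport:
    kept: list
    dropped: dict = field(default_factory=dict)   # feature -> reason string
    statistics: dict = field(default_factory=dict)  # feature -> r or IG
    rule: str = ""
    notes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "rule": self.rule,
                "kept": list(self.kept),
                "dropped": dict(self.dropped),
                "statistics": {k: float(v) for k, v in self.statistics.items()},
                "notes": self.notes,
            }, fh, indent=2)


def pearson_r(x, y) -> float:
    """Product-moment correlation on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise UndefinedCorrelationError("fewer than 3 pairwise-complete observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("constant input")
    return float((dx * dy).sum() / (sx * sy))


def prune_vs_target(table: pd.DataFrame, target, cutoff: float = 0.7) -> SelectionReport:
    """Drop features with |r(feature, target)| > cutoff, and the target itself.

    A strong negative correlation is as redundant as a positive one, so the
    absolute value is compared.
    """
    tgt = pd.Series(target, index=table.index) if not isinstance(target, pd.Series) else target
    kept, dropped, stats = [], {}, {}
    for col in table.columns:
        if tgt.name is not None and col == tgt.name:
            dropped[col] = "is the target"
            continue
        try:
            r = pearson_r(table[col].to_numpy(), tgt.to_numpy())
        except UndefinedCorrelationError:
            dropped[col] = "undefined correlation (constant or too few pairs)"
            continue
        stats[col] = r
        if abs(r) > cutoff:
            dropped[col] = f"|r|={abs(r):.3f} > {cutoff} vs target"
        else:
            kept.append(col)
    if not kept:
        warnings.warn("vs-target prune removed every feature", stacklevel=2)
    return SelectionReport(kept=kept, dropped=dropped, statistics=stats,
                           rule=f"vs-target |r| > {cutoff}")


def prune_pairwise(table: pd.DataFrame, cutoff: float = 0.7) -> SelectionReport:
    """Greedy scan in column order: drop a feature if |r| > cutoff with any
    already-kept feature; the earlier column wins."""
    kept, dropped, stats = [], {}, {}
    for col in table.columns:
        offender = None
        for prev in kept:
            try:
                r = pearson_r(table[col].to_numpy(), table[prev].to_numpy())
            except UndefinedCorrelationError:
                continue
            if abs(r) > cutoff:
                offender, stats[col] = prev, r
                break
        if offender is None:
            kept.append(col)
        else:
            dropped[col] = f"|r|={abs(stats[col]):.3f} > {cutoff} vs kept {offender!r}"
    return SelectionReport(kept=kept, dropped=dropped, statistics=stats,
                           rule=f"pairwise greedy |r| > {cutoff}")


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(feature, labels, n_bins: int = 10) -> float:
    """IG = H(labels) - sum_b p(b) H(labels | bin b), base-2 (bits).

    Continuous features are discretized into ``n_bins`` equal-frequency
    bins; features with at most ``n_bins`` distinct values (ordinal or
    categorical codes) are used as-is.  Rows with a missing feature value
    are excluded pairwise.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ZeroEntropyError("labels are single-class")
    distinct = np.unique(x)
    if len(distinct) <= n_bins:
        bins = np.searchsorted(distinct, x)
    else:
        edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
        bins = np.searchsorted(edges, x)
    h = _entropy(y)
    cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        cond += sel.mean() * _entropy(y[sel])
    return max(h - cond, 0.0)


def rank_by_information_gain(table: pd.DataFrame, labels, k: int = 50,
                             n_bins: int = 10) -> list:
    """Top-k features by information gain, descending; ties keep column order."""
    igs = {}
    for col in table.columns:
        igs[col] = information_gain(table[col].to_numpy(), labels, n_bins=n_bins)
    order = sorted(table.columns, key=lambda c: -igs[c])  # stable: ties by column order
    if k > len(order):
        warnings.warn(f"requested top {k} of only {len(order)} features", stacklevel=2)
        k = len(order)
    return order[:k]


def completeness_filter(table, min_fraction: float = 0.8):
    """Drop rows with a non-missing fraction below ``min_fraction`` (inclusive
    at the boundary: exactly 80% complete is kept)."""
    df = table.data if hasattr(table, "data") else table
    frac = df.notna().mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise EmptyTableError("completeness filter removed every row")
    out = df[keep]
    if hasattr(table, "data"):
        from .cohort import CohortTable
        return CohortTable(out, dict(table.kinds), dict(table.ordinal_ranges))
    return out
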