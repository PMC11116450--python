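#!/usr/bin/env python
"""Binarize the clinical descriptors by Youden-index grid search.

For each descriptor, every midpoint between consecutive observed values is
tried as a cut; a nested leave-one-out linear SVM on the remaining
descriptors classifies the resulting labels, and the cut maximizing
Youden's J on the pooled held-out predictions wins.  Descriptors whose
mean train accuracy falls below 0.75 are dropped as targets.
"""

import argparse
from pathlib import Path

from oa_stratify.binarization import binarize_cohort, write_thresholds
from oa_stratify.cohort import CohortTable
from oa_stratify.svm import SvmConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cohort = CohortTable.from_csv(RESULTS / "cohort.csv",
                                  sidecar=RESULTS / "cohort_meta.yaml")
    results = binarize_cohort(cohort, SvmConfig(c_grid=(1.0,), seed=args.seed))
    write_thresholds(results, RESULTS / "thresholds.yaml")

    print(f"{'descriptor':<12}{'threshold':>10}{'J':>8}{'train acc':>11}{'retained':>10}")
    for name, r in results.items():
        print(f"{name:<12}{r.threshold:>10.1f}{r.youden:>8.3f}"
              f"{r.mean_train_accuracy:>11.3f}{str(r.retained):>10}")
    mean_acc = sum(r.mean_train_accuracy for r in results.values()) / len(results)
    print(f"\nmean binarization train accuracy: {mean_acc:.3f}")
    print(f"wrote {RESULTS / 'thresholds.yaml'}")


if __name__ == "__main__":
    main()
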