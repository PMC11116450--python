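#!/usr/bin/env python
"""Run the 21 nested leave-one-out SVM classification tasks.

Each retained descriptor is classified from three input sets — the
remaining descriptors (51 subjects, 50 fits each), the 11 synovial-fluid
analytes, and the 8 simulated TF activations (25 subjects, 24 fits each,
paper-compatibility fold mode).  Fold-averaged normalized weights give the
importance matrices; pooled held-out decision values give the ROC-AUCs.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from oa_stratify.binarization import read_thresholds
from oa_stratify.cohort import CohortTable
from oa_stratify.svm import SvmConfig, importance_matrix, run_all_tasks

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cohort = CohortTable.from_csv(RESULTS / "cohort.csv",
                                  sidecar=RESULTS / "cohort_meta.yaml")
    thresholds = read_thresholds(RESULTS / "thresholds.yaml")
    tf = pd.read_csv(RESULTS / "tf_activations.csv", index_col=0)
    tf = tf.drop(columns="converged")

    reports = run_all_tasks(cohort, thresholds, tf, SvmConfig(seed=args.seed))
    with open(RESULTS / "classification_reports.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)

    total = sum(len(r.fold_results) for r in reports)
    print(f"{len(reports)} classification tasks, {total} model fits\n")
    print(f"{'task':<16}{'folds':>6}{'AUC':>8}{'top feature':>14}")
    for r in reports:
        top = r.feature_names[int(r.importances.argmax())]
        print(f"{r.task_id:<16}{len(r.fold_results):>6}{r.auc:>8.3f}{top:>14}")
    for input_set in ("clinical", "sf", "tf"):
        mat = importance_matrix(reports, input_set)
        mat.to_csv(RESULTS / f"importance_{input_set}.csv", lineterminator="\n")
    mean_tf_auc = sum(r.auc for r in reports if r.task_id.endswith("/tf")) / 7
    print(f"\nmean TF-input AUC: {mean_tf_auc:.3f}")
    print(f"wrote importance matrices and reports under {RESULTS}")


if __name__ == "__main__":
    main()
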