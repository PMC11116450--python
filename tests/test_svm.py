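"""Nested leave-one-out SVM pipeline: C tuning, fold bookkeeping, pooled
AUC, importance normalization, and task assembly."""

import numpy as np
import pandas as pd
import pytest

from oa_stratify.svm import (ClassifierReport, DegenerateLabelsError,
                             FoldResult, SvmConfig, importance,
                             importance_matrix, nested_loo, pooled_auc,
                             run_task, tune_C)


def brute_force_auc(scores, labels):
    """All-pairs counting oracle; ties contribute 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _folds_from(scores, labels):
    return [FoldResult(i, np.zeros(1), 0.0, 1.0, s, y, 1.0)
            for i, (s, y) in enumerate(zip(scores, labels))]


class TestPooledAuc:
    def test_perfectly_ordered(self):
        assert pooled_auc(_folds_from([1, 2, 3, 4], [0, 0, 1, 1])) == 1.0

    def test_perfectly_anti_ordered(self):
        assert pooled_auc(_folds_from([4, 3, 2, 1], [0, 0, 1, 1])) == 0.0

    def test_worked_example(self):
        assert pooled_auc(_folds_from([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])) == 0.75

    def test_ties_contribute_half(self):
        assert pooled_auc(_folds_from([1, 1], [0, 1])) == 0.5

    def test_single_class_pool_errors(self):
        with pytest.raises(DegenerateLabelsError):
            pooled_auc(_folds_from([1, 2], [1, 1]))

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(4, 15)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.0, 0.25, 0.5, 1.0, 2.0], size=n)  # force ties
            folds = _folds_from(scores, labels)
            assert pooled_auc(folds) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)


class TestTuneC:
    def test_separable_tie_resolves_to_smallest_C(self, separable_toy):
        X, y = separable_toy
        assert tune_C(X, y, SvmConfig()) == pytest.approx(1e-3)

    def test_single_value_grid_returned(self, separable_toy):
        X, y = separable_toy
        assert tune_C(X, y, SvmConfig(c_grid=(0.42,))) == 0.42

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 2, 30)
        cfg = SvmConfig(seed=5)
        assert tune_C(X, y, cfg) == tune_C(X, y, cfg)

    def test_single_class_errors(self):
        with pytest.raises(DegenerateLabelsError):
            tune_C(np.zeros((10, 2)), np.zeros(10, dtype=int), SvmConfig())


class TestNestedLoo:
    def test_paper_compat_fold_count_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((51, 3))
        y = np.tile([0, 1], 26)[:51]
        folds, _ = nested_loo(X, y, SvmConfig(c_grid=(1.0,), fold_mode="paper_compat"))
        assert len(folds) == 50

    def test_standard_fold_count_is_n(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((25, 3))
        y = np.tile([0, 1], 13)[:25]
        folds, _ = nested_loo(X, y, SvmConfig(c_grid=(1.0,), fold_mode="standard"))
        assert len(folds) == 25

    def test_separable_toy_held_out_decisions_correctly_signed(self, separable_toy):
        X, y = separable_toy
        folds, _ = nested_loo(X, y, SvmConfig(c_grid=(1.0,), fold_mode="standard"))
        for f in folds:
            assert (f.decision_value > 0) == bool(f.y_true)

    def test_both_classes_required(self):
        with pytest.raises(DegenerateLabelsError):
            nested_loo(np.zeros((10, 2)), np.ones(10, dtype=int), SvmConfig())

    def test_liblinear_backend_agrees_on_separable_toy(self, separable_toy):
        X, y = separable_toy
        folds, _ = nested_loo(X, y, SvmConfig(c_grid=(1.0,), backend="liblinear",
                                              fold_mode="standard"))
        assert pooled_auc(folds) == 1.0


class TestImportance:
    def test_single_fold_equal_magnitudes_map_to_one(self):
        folds = [FoldResult(0, np.array([2.0, -2.0]), 0.0, 1.0, 0.5, 1, 1.0)]
        imps, mean_w, zero = importance(folds)
        assert imps.tolist() == [1.0, 1.0]
        assert mean_w.tolist() == [2.0, -2.0]
        assert not zero

    def test_all_zero_weights_flagged(self):
        folds = [FoldResult(0, np.zeros(3), 0.0, 1.0, 0.5, 1, 1.0)]
        imps, _, zero = importance(folds)
        assert zero and imps.tolist() == [0.0, 0.0, 0.0]

    def test_min_max_normalization_range(self):
        folds = [FoldResult(i, np.array([3.0, 1.0, -2.0]), 0.0, 1.0, 0.5, 1, 1.0)
                 for i in range(3)]
        imps, _, _ = importance(folds)
        assert imps.max() == 1.0 and imps.min() == 0.0
        assert imps.tolist() == [1.0, 0.0, 0.5]

    def test_informative_feature_gets_top_importance(self):
        rng = np.random.default_rng(3)
        n = 50
        y = np.tile([0, 1], 25)
        X = rng.standard_normal((n, 10))
        X[:, 4] = 3.0 * y + rng.standard_normal(n)
        folds, _ = nested_loo(X, y, SvmConfig(c_grid=(1.0,)))
        imps, _, _ = importance(folds)
        assert imps[4] == 1.0


@pytest.fixture(scope="module")
def thresholds(study_cohort):
    # median-split thresholds: cheap, guarantees two classes everywhere
    return {c: {"threshold": float(study_cohort.data[c].median()) + 0.25, "retained": True}
            for c in study_cohort.columns_of_kind("clinical")}


class TestRunTask:
    def test_target_never_in_its_own_features(self, study_cohort, thresholds):
        rep = run_task(study_cohort, "JP", "clinical", thresholds, SvmConfig(c_grid=(1.0,)))
        assert "JP" not in rep.feature_names

    def test_clinical_task_has_51_subjects_50_folds(self, study_cohort, thresholds):
        rep = run_task(study_cohort, "SE", "clinical", thresholds, SvmConfig(c_grid=(1.0,)))
        assert len(rep.fold_results) == 50

    def test_sf_task_restricted_to_subset_24_folds(self, study_cohort, thresholds):
        rep = run_task(study_cohort, "SE", "sf", thresholds, SvmConfig(c_grid=(1.0,)))
        assert len(rep.fold_results) == 24
        assert len(rep.feature_names) == 11

    def test_tf_task_requires_table(self, study_cohort, thresholds):
        with pytest.raises(ValueError, match="TF activation"):
            run_task(study_cohort, "SE", "tf", thresholds, SvmConfig(c_grid=(1.0,)))

    def test_unknown_input_set_rejected(self, study_cohort, thresholds):
        with pytest.raises(ValueError, match="input set"):
            run_task(study_cohort, "SE", "proteome", thresholds)

    def test_planted_analyte_driver_recovered_in_sf_task(self):
        # SY is driven primarily by MCP1 in the study structure
        from oa_stratify.cohort import generate_cohort
        from oa_stratify.pipeline import study_cohort_config

        hits = 0
        for seed in range(5):
            cohort = generate_cohort(study_cohort_config(seed))
            thr = {"SY": {"threshold": float(cohort.data["SY"].median()) + 0.25}}
            rep = run_task(cohort, "SY", "sf", thr, SvmConfig(c_grid=(1.0,), seed=seed))
            top = rep.feature_names[int(np.argmax(rep.importances))]
            hits += top in ("MCP1", "LEPTIN")
        assert hits >= 4


class TestImportanceMatrix:
    def _report(self, target, feats, imps):
        return ClassifierReport(
            task_id=f"{target}/clinical", feature_names=feats,
            fold_results=[FoldResult(0, np.zeros(len(feats)), 0, 1, 0.5, 1, 1.0)],
            mean_weights=np.zeros(len(feats)), importances=np.asarray(imps),
            auc=0.5, mean_train_accuracy=1.0)

    def test_shape_and_omitted_cells(self):
        reports = [
            self._report("JP", ["FU", "RI"], [1.0, 0.2]),
            self._report("FU", ["JP", "RI"], [0.3, 1.0]),
        ]
        mat = importance_matrix(reports, "clinical")
        assert mat.shape == (2, 3)
        assert np.isnan(mat.loc["JP", "JP"])  # the target's own cell is blank
        assert mat.loc["JP", "FU"] == 1.0

    def test_entries_in_unit_interval_with_row_max_one(self, study_cohort):
        thr = {c: {"threshold": float(study_cohort.data[c].median()) + 0.25}
               for c in ("JP", "FU")}
        reports = [run_task(study_cohort, t, "clinical", thr, SvmConfig(c_grid=(1.0,)))
                   for t in ("JP", "FU")]
        mat = importance_matrix(reports, "clinical")
        vals = mat.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()
        assert np.nanmax(vals, axis=1) == pytest.approx([1.0, 1.0])
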