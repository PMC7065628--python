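"""Nested cross-validation: splits, leakage control, metrics, grids."""

import numpy as np
import pandas as pd
import pytest

from oracles import exhaustive_metrics as _exhaustive_metrics

from tcellact.evaluation import (CellDataset, SplitPlan, compute_metrics,
                                 grid_search, holdout_final_test,
                                 make_early_stop_split, make_outer_splits,
                                 run_nested_cv)

DONORS = ["donor1", "donor2", "donor3", "donor5", "donor6"]


def _synthetic_label_dataset(counts: dict[str, tuple[int, int]]):
    """Dataset with given per-donor (activated, quiescent) counts and blank
    images: enough for label-only models."""
    rows = []
    for donor, (n_act, n_qui) in counts.items():
        for i in range(n_act):
            rows.append((donor, "activated"))
        for i in range(n_qui):
            rows.append((donor, "quiescent"))
    meta = pd.DataFrame({
        "donor_id": [r[0] for r in rows],
        "label": [r[1] for r in rows],
        "augmentation_tag": "original",
        "source_id": [f"c{i}" for i in range(len(rows))],
    })
    images = np.zeros((len(rows), 2, 2), dtype=np.uint8)
    return CellDataset(images, meta)


class TestSplits:
    def test_five_by_four_structure(self):
        plans = make_outer_splits(DONORS + ["donor4"], holdout_donor="donor4")
        assert len(plans) == 5
        for plan in plans:
            assert len(plan.inner_folds) == 4
            for train, val in plan.inner_folds:
                assert len(train) == 3
                assert plan.outer_test_donor not in train
                assert plan.outer_test_donor != val
                assert "donor4" not in train and val != "donor4"

    def test_three_donors_two_inner_folds(self):
        plans = make_outer_splits(["a", "b", "c"])
        assert len(plans) == 3
        assert all(len(p.inner_folds) == 2 for p in plans)

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            make_outer_splits(["a", "b"])

    def test_leaky_plan_construction_rejected(self):
        with pytest.raises(ValueError, match="leaks"):
            SplitPlan(outer_test_donor="a",
                      inner_folds=[(("a", "b"), "c")])


class TestEarlyStopSplit:
    def _augmented_dataset(self, n_sources=1000):
        tags = ["original", "rot90", "rot180", "rot270", "flip_h", "flip_v"]
        meta = pd.DataFrame({
            "donor_id": "d1",
            "label": "activated",
            "augmentation_tag": tags * n_sources,
            "source_id": [f"s{i}" for i in range(n_sources)
                          for _ in tags],
        })
        return CellDataset(np.zeros((len(meta), 2, 2), np.uint8), meta)

    def test_quarter_rule_arithmetic(self):
        """1000 sources (6000 rows) -> 250 early-stop originals and
        750 x 6 = 4500 training rows."""
        ds = self._augmented_dataset(1000)
        train, early = make_early_stop_split(ds, ds.rows(), seed=0)
        assert len(early) == 250
        assert len(train) == 4500
        assert (ds.meta.iloc[early]["augmentation_tag"] == "original").all()

    def test_fixed_seed_reproducible(self):
        ds = self._augmented_dataset(40)
        a = make_early_stop_split(ds, ds.rows(), seed=9)
        b = make_early_stop_split(ds, ds.rows(), seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_no_augmented_copy_of_early_stop_cell_in_training(self):
        ds = self._augmented_dataset(40)
        train, early = make_early_stop_split(ds, ds.rows(), seed=3)
        early_sources = set(ds.meta.iloc[early]["source_id"])
        train_sources = set(ds.meta.iloc[train]["source_id"])
        assert not early_sources & train_sources

    def test_no_unaugmented_cells_is_error(self):
        ds = self._augmented_dataset(4)
        rows = ds.rows()[ds.meta["augmentation_tag"] != "original"]
        with pytest.raises(ValueError, match="unaugmented"):
            make_early_stop_split(ds, rows, seed=0)


class TestComputeMetrics:
    def test_holdout_donor_confusion_arithmetic(self):
        """482 activated / 1569 quiescent with 4 FP and 20 FN give
        accuracy 98.83%, precision 99.14%, recall 95.85%."""
        labels = np.array([1] * 482 + [0] * 1569)
        scores = np.empty(len(labels))
        scores[:462] = 0.9     # true positives
        scores[462:482] = 0.1  # 20 false negatives
        scores[482:486] = 0.9  # 4 false positives
        scores[486:] = 0.1     # true negatives
        r = compute_metrics(scores, labels)
        assert (r.tp, r.fp, r.tn, r.fn) == (462, 4, 1565, 20)
        assert round(r.accuracy * 100, 2) == 98.83
        assert round(r.precision * 100, 2) == 99.14
        assert round(r.recall * 100, 2) == 95.85

    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        r = compute_metrics(np.array([0.1, 0.2, 0.8, 0.9]), labels)
        assert r.auc == 1.0 and r.average_precision == 1.0

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            r = compute_metrics(scores, labels)
            o = _exhaustive_metrics(scores, labels)
            for k, v in o.items():
                assert getattr(r, k) == pytest.approx(v), k

    def test_single_class_flagged(self):
        r = compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
        assert not r.curves_defined
        assert np.isnan(r.auc)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1.2]), np.array([1]))


class TestGridSearch:
    def _plan(self):
        return make_outer_splits(["a", "b", "c", "d"])[0]

    def _dataset(self, rng):
        counts = {d: (30, 30) for d in "abcd"}
        ds = _synthetic_label_dataset(counts)
        # one informative pixel so lasso grids order meaningfully
        ds.images = rng.integers(0, 50, size=(len(ds), 2, 2)).astype(np.uint8)
        ds.images[ds.y == 1] += 120
        ds.masks = np.ones_like(ds.images, dtype=bool)
        return ds

    def test_single_config_selected(self):
        ds = _synthetic_label_dataset({d: (20, 20) for d in "abcd"})
        gr = grid_search(self._plan(), [{}], ds, "frequency")
        assert gr.selected_index == 0

    def test_tie_breaks_to_first_listed(self):
        ds = _synthetic_label_dataset({d: (20, 20) for d in "abcd"})
        gr = grid_search(self._plan(), [{}, {}], ds, "frequency")
        assert gr.mean_ap[0] == gr.mean_ap[1]
        assert gr.selected_index == 0

    def test_dominating_config_selected(self, rng):
        ds = self._dataset(rng)
        grid = [{"lambda_": 1e5}, {"lambda_": 0.01}]  # null vs useful model
        gr = grid_search(self._plan(), grid, ds, "lasso_scalar")
        assert gr.selected_index == 1
        assert all(b >= a for a, b in zip(*gr.per_fold_ap))

    def test_empty_grid_rejected(self):
        ds = _synthetic_label_dataset({d: (5, 5) for d in "abcd"})
        with pytest.raises(ValueError, match="empty"):
            grid_search(self._plan(), [], ds, "frequency")

    def test_invalid_config_fails_before_training(self, rng):
        ds = self._dataset(rng)
        with pytest.raises(TypeError):
            grid_search(self._plan(), [{"no_such_param": 1}], ds,
                        "lasso_scalar")


class TestNestedCV:
    # Post-filter per-donor counts of the real study (arithmetic inputs)
    TABLE_COUNTS = {
        "donor1": (235, 1551), "donor2": (647, 141), "donor3": (446, 1238),
        "donor5": (683, 246), "donor6": (442, 580),
    }

    def test_frequency_reproduces_closed_form_mean_accuracy(self):
        """Nested CV of the frequency model on the real per-donor counts
        equals the closed-form leave-one-donor-out value, 37.56%."""
        ds = _synthetic_label_dataset(self.TABLE_COUNTS)
        res = run_nested_cv(ds, "frequency", [{}], seed=0)
        mean_acc = res["summary"].loc["mean", "accuracy"]
        # closed form from the counts
        accs = []
        for test, (a_t, q_t) in self.TABLE_COUNTS.items():
            a = sum(v[0] for d, v in self.TABLE_COUNTS.items() if d != test)
            q = sum(v[1] for d, v in self.TABLE_COUNTS.items() if d != test)
            pred_act = a / (a + q) >= 0.5
            accs.append((a_t if pred_act else q_t) / (a_t + q_t))
        assert mean_acc == pytest.approx(np.mean(accs))
        assert round(mean_acc * 100, 2) == 37.56

    def test_lasso_cp_high_auc_on_separable_cohort(self, six_donor_dataset):
        res = run_nested_cv(six_donor_dataset, "lasso_cp",
                            [{"lambda_": 0.01}, {"lambda_": 0.1}],
                            holdout_donor="donor4", seed=1)
        assert res["summary"].loc["mean", "auc"] >= 0.9

    def test_no_donor_leakage_audited(self, six_donor_dataset):
        ds = six_donor_dataset
        ds.audit_log.clear()
        run_nested_cv(ds, "frequency", [{}], holdout_donor="donor4", seed=0)
        test_donors = [e["donors"][0] for e in ds.audit_log
                       if e["event"] == "outer_test"]
        assert sorted(test_donors) == [d for d in ds.donors if d != "donor4"]
        for event in ds.audit_log:
            if event["event"] in ("inner_train", "outer_train"):
                assert event["test_donor"] not in event["donors"]
                assert "donor4" not in event["donors"]

    def test_augmented_rows_never_evaluated(self, six_donor_dataset):
        ds = six_donor_dataset
        for donors in (["donor1"], ["donor2"]):
            rows = ds.rows(donors, original_only=True)
            assert (ds.meta.iloc[rows]["augmentation_tag"] == "original").all()
        # test rows in nested CV are exactly the original rows
        res = run_nested_cv(ds, "frequency", [{}], holdout_donor="donor4",
                            seed=0)
        for donor, report in res["per_donor"].items():
            assert report.n == len(ds.rows([donor], original_only=True))


class TestHoldout:
    def test_holdout_untouched_then_tested_once(self, six_donor_dataset):
        ds = six_donor_dataset
        ds.audit_log.clear()
        run_nested_cv(ds, "frequency", [{}], holdout_donor="donor4", seed=0)
        out = holdout_final_test(ds, "donor4", "lasso_cp",
                                 [{"lambda_": 0.1}], seed=0)
        tests = [e for e in ds.audit_log if e["event"] == "outer_test"
                 and e["donors"] == ["donor4"]]
        assert len(tests) == 1
        r = out["report"]
        assert r.tp + r.fn + r.fp + r.tn == len(
            ds.rows(["donor4"], original_only=True))
        # well-separated synthetic cohort: near-perfect holdout accuracy
        assert r.accuracy > 0.95

    def test_prior_access_is_hard_failure(self, six_donor_dataset):
        ds = six_donor_dataset
        ds.audit_log.clear()
        ds.log("inner_train", ["donor4", "donor1"])
        with pytest.raises(RuntimeError, match="accessed earlier"):
            holdout_final_test(ds, "donor4", "frequency", [{}])
        ds.audit_log.clear()
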