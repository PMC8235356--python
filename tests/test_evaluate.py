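"""Partial-dropping cross-validation, metric formulas and the sweep
harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from ventasync import evaluate as ev
from ventasync.synth import generate_dataset


class TestFoldPlan:
    def test_full_retention(self):
        plan = ev.make_partial_dropping_folds(list(range(100)), 5, 1.0, seed=0)
        for f in range(5):
            fold = plan.fold(f)
            assert len(fold["M_ids"]) == 80
            assert len(fold["M1_ids"]) == 80
            assert fold["M2_ids"] == []

    def test_floor_retention_size(self):
        plan = ev.make_partial_dropping_folds(list(range(100)), 5, 0.1, seed=0)
        assert all(len(plan.fold(f)["M1_ids"]) == 8 for f in range(5))

    @pytest.mark.parametrize("n", [50, 100, 103])
    @pytest.mark.parametrize("prr", [1.0, 0.1])
    def test_partition_disjointness_exhaustive(self, n, prr):
        ids = [f"c{i}" for i in range(n)]
        plan = ev.make_partial_dropping_folds(ids, 5, prr, seed=3)
        all_test = []
        for f in range(5):
            fold = plan.fold(f)
            test, pool = set(fold["test_ids"]), set(fold["M_ids"])
            m1, m2 = set(fold["M1_ids"]), set(fold["M2_ids"])
            assert test | pool == set(ids)
            assert not test & pool
            assert m1 <= pool and m2 == pool - m1
            assert not m1 & test
            expect = int(np.floor(prr * len(pool)))
            assert len(m1) == expect
            all_test.extend(fold["test_ids"])
        assert sorted(all_test) == sorted(ids)  # folds partition the ids

    def test_round_mode(self):
        ids = list(range(103))
        plan = ev.make_partial_dropping_folds(ids, 5, 0.1, seed=1,
                                              int_mode="round")
        sizes = {len(plan.fold(f)["M1_ids"]) for f in range(5)}
        assert sizes <= {round(0.1 * 82), round(0.1 * 83)}

    def test_stratified_retention_keeps_both_classes(self):
        ids = list(range(100))
        labels = [1 if i < 20 else 0 for i in ids]
        plan = ev.make_partial_dropping_folds(ids, 5, 0.05, seed=2,
                                              labels=labels)
        for f in range(5):
            kept = [labels[i] for i in plan.fold(f)["M1_ids"]]
            assert set(kept) == {0, 1}

    def test_determinism(self):
        a = ev.make_partial_dropping_folds(list(range(50)), 5, 0.5, seed=9)
        b = ev.make_partial_dropping_folds(list(range(50)), 5, 0.5, seed=9)
        assert a.fold_assignments == b.fold_assignments
        assert all(a.fold(f) == b.fold(f) for f in range(5))

    def test_too_small_retention_rejected(self):
        with pytest.raises(ValueError, match="70/30"):
            ev.make_partial_dropping_folds(list(range(100)), 5, 0.01)


class TestMetrics:
    def test_perfect_classifier(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1) == (1, 1, 1, 1)

    def test_worked_example(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=30, fn=10, tn=40, fp=20))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.70)
        assert m.f1 == pytest.approx(2 * 0.75 * (2 / 3) / (0.75 + 2 / 3),
                                     abs=1e-4)

    def test_undefined_ratios_are_nan_not_zero(self):
        m = ev.compute_metrics(ev.ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m.sensitivity) and np.isnan(m.f1)
        assert m.specificity == 0.5
        m2 = ev.compute_metrics(ev.ConfusionCounts(tp=5, fn=5, tn=0, fp=0))
        assert np.isnan(m2.specificity)

    def test_against_formula_oracle_1000_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 200, size=4)
            m = ev.compute_metrics(ev.ConfusionCounts(int(tp), int(tn),
                                                      int(fp), int(fn)))
            # independent straight-from-formula re-implementation
            acc = (tp + tn) / (tp + tn + fp + fn)
            sen = tp / (tp + fn)
            spe = tn / (tn + fp)
            f1 = 2 * sen * spe / (sen + spe)
            assert abs(m.accuracy - acc) < 1e-12
            assert abs(m.sensitivity - sen) < 1e-12
            assert abs(m.specificity - spe) < 1e-12
            assert abs(m.f1 - f1) < 1e-12

    @hsettings(max_examples=100, deadline=None)
    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    def test_metric_identities(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = ev.compute_metrics(ev.ConfusionCounts(tp, tn, fp, fn))
        sw = ev.compute_metrics(ev.ConfusionCounts(tn, tp, fn, fp))
        assert m.accuracy == pytest.approx(sw.accuracy)
        if not (np.isnan(m.sensitivity) or np.isnan(m.specificity)):
            lo = min(m.sensitivity, m.specificity)
            hi = max(m.sensitivity, m.specificity)
            assert lo - 1e-12 <= m.f1 <= hi + 1e-12


class TestModelZoo:
    def test_every_zoo_name_parses_uniquely(self):
        names = ev.zoo_model_names()
        assert len(names) == 14  # 12 CNN variants + Manual_SVM + LSTM
        assert len(set(names)) == 14
        for name in names:
            info = ev.parse_model_name(name)
            assert info["kind"] in ("cnn", "manual_svm", "lstm")

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ev.parse_model_name("Pr_ResNet_DC")


@pytest.fixture(scope="module")
def sweep():
    rec = generate_dataset({"DT": 10, "IEE": 0, "OTHER": 20},
                           noise_sd=0.02, seed=1)
    return ev.run_prr_experiment(
        rec, ["Pr_Tiny_DC", "Rd_Tiny_DC"], [1.0, 0.5, 0.2], k=5,
        seeds=(0,), pos_label="DT", head_epochs=30, pretrain_epochs=3,
        pretrain_n=8)


class TestSweepHarness:
    def test_grid_row_count(self, sweep):
        assert len(sweep) == 2 * 3 * 5 * 1

    def test_no_leakage_between_test_and_training(self):
        rec = generate_dataset({"DT": 10, "IEE": 0, "OTHER": 20},
                               noise_sd=0.0, seed=2)
        data = ev.binary_task_arrays(rec, "DT")
        plan = ev.make_partial_dropping_folds(data["ids"], 5, 0.5, seed=0,
                                              labels=list(data["y"]))
        for f in range(5):
            fold = plan.fold(f)
            assert not set(fold["test_ids"]) & set(fold["M1_ids"])

    def test_summary_shape(self, sweep):
        s = ev.summarize(sweep)
        assert set(s["model_name"]) == {"Pr_Tiny_DC", "Rd_Tiny_DC"}
        assert len(s) == 6
        assert "f1_mean" in s.columns

    def test_confusion_counts_cover_test_fold(self, sweep):
        n_eval = sweep[["tp", "tn", "fp", "fn"]].sum(axis=1)
        # each test fold holds 40/5 = 8 cycles
        assert (n_eval == 8).all()
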