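"""Cross-validation partitioning, metrics, ROC, and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vfforecast as vf
from vfforecast.evaluation import compare_algorithms_anova

from oracles import oneway_f, rank_auc, welch_t

LABELS_55 = np.array([vf.VF] * 27 + [vf.CONTROL] * 28)


class TestMakeFolds:
    def test_55_samples_into_10_folds(self):
        folds = vf.make_folds(LABELS_55, k=10, repeats=3, seed=0)
        for repeat in folds:
            sizes = sorted(len(f) for f in repeat)
            assert set(sizes) == {5, 6}
            union = np.concatenate(repeat)
            assert np.array_equal(np.sort(union), np.arange(55))

    def test_stratification_preserves_balance(self):
        folds = vf.make_folds(LABELS_55, k=10, repeats=1, seed=1)[0]
        for f in folds:
            n_vf = np.count_nonzero(LABELS_55[f] == vf.VF)
            assert n_vf in (2, 3)

    def test_same_seed_reproduces_assignment(self):
        a = vf.make_folds(LABELS_55, seed=5)
        b = vf.make_folds(LABELS_55, seed=5)
        for ra, rb in zip(a, b):
            for fa, fb in zip(ra, rb):
                assert np.array_equal(fa, fb)

    def test_repeats_differ(self):
        folds = vf.make_folds(LABELS_55, k=10, repeats=2, seed=2)
        assert any(not np.array_equal(a, b)
                   for a, b in zip(folds[0], folds[1]))

    def test_tiny_class_falls_back_with_warning(self):
        labels = np.array([vf.VF] * 3 + [vf.CONTROL] * 17)
        with pytest.warns(UserWarning):
            folds = vf.make_folds(labels, k=10, repeats=1, seed=0)
        assert np.array_equal(np.sort(np.concatenate(folds[0])), np.arange(20))


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        truth = [vf.VF] * 10 + [vf.CONTROL] * 10
        pred = [vf.VF] * 8 + [vf.CONTROL] * 2 + [vf.CONTROL] * 9 + [vf.VF]
        sens, spec, acc = vf.confusion_metrics(pred, truth)
        assert (sens, spec, acc) == (80.0, 90.0, 85.0)

    def test_perfect_predictions(self):
        truth = [vf.VF, vf.CONTROL, vf.VF]
        assert vf.confusion_metrics(truth, truth) == (100.0, 100.0, 100.0)

    def test_all_control_predictions(self):
        truth = [vf.VF] * 5 + [vf.CONTROL] * 5
        pred = [vf.CONTROL] * 10
        assert vf.confusion_metrics(pred, truth) == (0.0, 100.0, 50.0)

    def test_no_positives_flagged(self):
        sens, spec, acc = vf.confusion_metrics([vf.CONTROL], [vf.CONTROL])
        assert np.isnan(sens) and spec == 100.0


class TestROC:
    def test_perfect_separation(self):
        truth = [vf.CONTROL, vf.CONTROL, vf.VF, vf.VF]
        auc, _, _ = vf.roc_auc([0.1, 0.2, 0.8, 0.9], truth)
        assert auc == 1.0

    def test_worked_four_sample_example(self):
        auc, _, _ = vf.roc_auc([0.1, 0.4, 0.35, 0.8],
                               [vf.CONTROL, vf.CONTROL, vf.VF, vf.VF])
        assert auc == pytest.approx(0.75)

    def test_trapezoid_equals_rank_auc(self, rng):
        for _ in range(1000):
            n = int(rng.integers(10, 40))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            truth = np.where(labels == 1, vf.VF, vf.CONTROL)
            auc, _, _ = vf.roc_auc(scores, truth)
            assert auc == pytest.approx(rank_auc(scores, labels), abs=1e-12)

    def test_label_independent_scores_near_half(self, rng):
        truth = np.where(rng.integers(0, 2, size=200) == 1, vf.VF, vf.CONTROL)
        auc, _, _ = vf.roc_auc(rng.normal(size=200), truth)
        assert abs(auc - 0.5) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(vf.InsufficientDataError):
            vf.roc_auc([0.1, 0.9], [vf.VF, vf.VF])


class TestTTest:
    def test_identical_groups(self):
        t, p = vf.compare_groups_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert abs(t) < 1e-12 and p == pytest.approx(1.0)

    def test_identical_constant_groups_by_convention(self):
        assert vf.compare_groups_ttest([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)

    def test_large_effect_power(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(5, 1, 30)
        _, p = vf.compare_groups_ttest(x, y)
        assert p < 1e-10

    def test_matches_textbook_welch_formula(self):
        x = [12.1, 14.3, 13.8, 15.2, 12.9]
        y = [10.2, 9.8, 11.5, 10.9]
        t, p = vf.compare_groups_ttest(x, y)
        t_hand, df_hand = welch_t(x, y)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), rel=1e-9)


class TestAnova:
    def test_identical_columns_give_zero_f(self):
        col = np.array([70.0, 72.0, 68.0, 71.0])
        table = pd.DataFrame({a: col for a in ("ANN", "SVM", "KNN")})
        res = compare_algorithms_anova(table)
        assert res.f == 0.0 and res.p == 1.0
        assert not res.tukey["reject"].any()

    def test_f_matches_hand_computation_on_toy_table(self):
        groups = [[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0],
                  [6.0, 7.0, 8.0, 9.0]]
        table = pd.DataFrame({"a": groups[0], "b": groups[1], "c": groups[2]})
        res = compare_algorithms_anova(table)
        assert res.f == pytest.approx(oneway_f(groups), rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 9)

    def test_tukey_flags_exactly_the_shifted_group(self, rng):
        base = {a: rng.normal(70, 2, size=40) for a in ("ANN", "SVM", "KNN", "RF")}
        base["NB"] = rng.normal(76, 2, size=40)  # shifted by 3 within-SDs
        res = compare_algorithms_anova(pd.DataFrame(base))
        rejected = res.tukey[res.tukey["reject"].astype(bool)]
        flagged = set(map(frozenset, zip(rejected["group1"], rejected["group2"])))
        expected = {frozenset({"NB", a}) for a in ("ANN", "SVM", "KNN", "RF")}
        assert flagged == expected

    def test_unbalanced_design_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(vf.InvalidParameterError):
            compare_algorithms_anova(table)


@pytest.fixture(scope="module")
def separable_features():
    from vfforecast.pipeline import extract_features
    cohort = vf.generate_cohort(27, 28, *vf.preset_params("separable"),
                                seed=33)
    table, _ = extract_features([c.record for c in cohort])
    return table


class TestRunExperiment:
    def test_separable_qrs_ann_is_nearly_perfect(self, separable_features):
        rep = vf.run_experiment(separable_features,
                                separable_features["label"],
                                feature_set="QRS-4", algorithm="ANN",
                                repeats=2, seed=1)
        assert rep.summary["accuracy_mean"] >= 95.0

    def test_accuracy_identity_per_fold(self, separable_features):
        rep = vf.run_experiment(separable_features,
                                separable_features["label"],
                                feature_set="QRS-4", algorithm="NB",
                                repeats=2, seed=2)
        labels = separable_features["label"].to_numpy()
        folds = vf.make_folds(labels, k=10, repeats=2, seed=2)
        for (_, row), test_idx in zip(rep.fold_metrics.iterrows(),
                                      [f for rep_f in folds for f in rep_f]):
            p = np.count_nonzero(labels[test_idx] == vf.VF)
            n = test_idx.size - p
            sens = row["sensitivity"] if p else 0.0
            spec = row["specificity"] if n else 0.0
            assert row["accuracy"] == pytest.approx(
                (sens * p + spec * n) / (p + n))

    def test_combined_feature_set_runs_with_15_inputs(self, separable_features):
        rep = vf.run_experiment(separable_features,
                                separable_features["label"],
                                feature_set="combined-15", algorithm="NB",
                                repeats=1, seed=3)
        assert len(rep.feature_names) == 15
        assert 0 <= rep.summary["accuracy_mean"] <= 100

    def test_global_scaler_mode_runs(self, separable_features):
        rep = vf.run_experiment(separable_features,
                                separable_features["label"],
                                feature_set="QRS-4", algorithm="NB",
                                repeats=1, seed=4, scaler_scope="global")
        assert rep.config["scaler_scope"] == "global"

    def test_missing_feature_column_rejected(self, separable_features):
        broken = separable_features.drop(columns=["SDNN"])
        with pytest.raises(vf.InvalidParameterError):
            vf.run_experiment(broken, broken["label"], feature_set="HRV-11",
                              algorithm="NB")
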