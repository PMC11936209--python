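"""Augmentation experiment: metric wiring, scenario construction,
classifier behaviour on separable classes, efficacy comparison."""

import numpy as np
import pytest

from beatbench.augment import (
    ClassificationReport,
    ClassifierConfig,
    ScenarioSizes,
    efficacy_report,
    make_experiment_datasets,
    train_and_evaluate,
)
from beatbench.core import BeatSet
from beatbench.simulate import synth_beatset

SMALL = ScenarioSizes(balanced=(150, 150), imbalanced=(15, 150),
                      augmented=(150, 150), test=(50, 50))
FAST = ClassifierConfig()  # scaled preset defaults: 10 epochs, batch 32


@pytest.fixture(scope="module")
def pools(normal_params, lbbb_params):
    n_needed = 150 + 50
    pn = synth_beatset(normal_params, n_needed, seed=301)
    pl = synth_beatset(lbbb_params, n_needed + 50, seed=302)
    pool_min = BeatSet(pn.data, ["N"] * pn.count)
    pool_maj = BeatSet(pl.data, ["L"] * pl.count)
    synth = synth_beatset(normal_params, 150, seed=303)
    return pool_min, pool_maj, synth


@pytest.fixture(scope="module")
def datasets(pools):
    pool_min, pool_maj, synth = pools
    return make_experiment_datasets(pool_min, pool_maj, synth, SMALL, seed=17)


class TestReports:
    def test_perfect_predictor_metrics(self):
        y = ["N"] * 5 + ["L"] * 7
        rep = ClassificationReport.from_predictions(y, y)
        assert rep.accuracy == 1.0
        assert rep.recall == {"L": 1.0, "N": 1.0}
        cm = np.array(rep.confusion)
        assert cm[0, 0] == 7 and cm[1, 1] == 5 and cm.sum() == 12

    def test_confusion_marginals_match_supports(self, rng):
        y_true = [("N" if v > 0 else "L") for v in rng.standard_normal(60)]
        y_pred = [("N" if v > 0 else "L") for v in rng.standard_normal(60)]
        rep = ClassificationReport.from_predictions(y_true, y_pred)
        cm = np.array(rep.confusion)
        for i, cl in enumerate(rep.classes):
            assert cm[i].sum() == rep.support[cl]
        assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())

    def test_weighted_f1_is_support_weighted_mean(self, rng):
        y_true = [("N" if v > 0.3 else "L") for v in rng.standard_normal(80)]
        y_pred = [("N" if v > 0 else "L") for v in rng.standard_normal(80)]
        rep = ClassificationReport.from_predictions(y_true, y_pred)
        supports = np.array([rep.support[c] for c in rep.classes])
        f1 = np.array([rep.f1[c] for c in rep.classes])
        expected = float((supports * f1).sum() / supports.sum())
        assert rep.weighted_avg["f1"] == pytest.approx(expected, abs=1e-9)

    def test_json_round_trip(self):
        rep = ClassificationReport.from_predictions(["N", "L", "N"], ["N", "L", "L"])
        back = ClassificationReport.from_json(rep.to_json())
        assert back == rep


class TestScenarioConstruction:
    def test_counts_match_requested_sizes(self, datasets):
        assert datasets["balanced"].count == 300
        assert datasets["imbalanced"].count == 165
        assert datasets["augmented"].count == 300
        assert datasets["test"].count == 100
        assert datasets["imbalanced"].labels.count("N") == 15

    def test_test_set_disjoint_from_training_sets(self, datasets):
        test_rows = {r.tobytes() for r in datasets["test"].data}
        for scen in ("balanced", "imbalanced", "augmented"):
            train_rows = {r.tobytes() for r in datasets[scen].data}
            assert not test_rows & train_rows

    def test_construction_is_seed_deterministic(self, pools):
        pool_min, pool_maj, synth = pools
        a = make_experiment_datasets(pool_min, pool_maj, synth, SMALL, seed=17)
        b = make_experiment_datasets(pool_min, pool_maj, synth, SMALL, seed=17)
        for scen in a:
            np.testing.assert_array_equal(a[scen].data, b[scen].data)
            assert a[scen].labels == b[scen].labels

    def test_augmented_reuses_imbalanced_real_minority(self, datasets):
        imb_minority = {r.tobytes() for r, l in zip(datasets["imbalanced"].data,
                                                    datasets["imbalanced"].labels) if l == "N"}
        aug_rows = {r.tobytes() for r in datasets["augmented"].data}
        assert imb_minority <= aug_rows

    def test_insufficient_pool_raises_named_shortfall(self, pools):
        pool_min, pool_maj, synth = pools
        tiny = BeatSet(pool_min.data[:20], ["N"] * 20)
        with pytest.raises(ValueError, match="minority pool too small"):
            make_experiment_datasets(tiny, pool_maj, synth, SMALL, seed=1)

    def test_pools_must_have_distinct_labels(self, pools):
        pool_min, _, synth = pools
        with pytest.raises(ValueError, match="distinct"):
            make_experiment_datasets(pool_min, pool_min, synth, SMALL, seed=1)


class TestClassifier:
    def test_balanced_training_recovers_minority(self, datasets):
        rep = train_and_evaluate(datasets["balanced"], datasets["test"], FAST, seed=21)
        assert rep.recall["N"] >= 0.9

    def test_imbalanced_training_hurts_minority_recall(self, datasets):
        balanced = train_and_evaluate(datasets["balanced"], datasets["test"], FAST, seed=21)
        imbalanced = train_and_evaluate(datasets["imbalanced"], datasets["test"], FAST, seed=21)
        assert imbalanced.recall["N"] < balanced.recall["N"]

    def test_single_class_test_set_rejected(self, datasets, rng):
        bad_test = BeatSet(rng.standard_normal((10, 256)), ["N"] * 10)
        with pytest.raises(ValueError, match="both classes"):
            train_and_evaluate(datasets["balanced"], bad_test, FAST, seed=1)

    def test_unlabeled_sets_rejected(self, datasets, rng):
        unlabeled = BeatSet(rng.standard_normal((10, 256)))
        with pytest.raises(ValueError, match="labeled"):
            train_and_evaluate(unlabeled, datasets["test"], FAST, seed=1)


class TestEfficacyReport:
    def _reports(self, recalls):
        out = {}
        for scen, rec in recalls.items():
            n = 20
            correct_n = int(round(rec * 10))
            y_true = ["N"] * 10 + ["L"] * 10
            y_pred = ["N"] * correct_n + ["L"] * (10 - correct_n) + ["L"] * 10
            out[scen] = ClassificationReport.from_predictions(y_true, y_pred)
        return out

    def test_ordering_flag_true_when_augmentation_helps(self):
        reports = self._reports({"balanced": 1.0, "imbalanced": 0.1, "augmented": 0.9})
        summary = efficacy_report(reports, minority_label="N")
        assert summary["augmentation_restores_recall"] is True
        assert summary["minority_recall_imbalanced"] == pytest.approx(0.1)

    def test_ordering_flag_false_for_identical_reports(self):
        reports = self._reports({"balanced": 0.5, "imbalanced": 0.5, "augmented": 0.5})
        assert efficacy_report(reports, "N")["augmentation_restores_recall"] is False

    def test_missing_scenario_rejected(self):
        reports = self._reports({"balanced": 1.0, "imbalanced": 0.1, "augmented": 0.9})
        del reports["augmented"]
        with pytest.raises(ValueError, match="augmented"):
            efficacy_report(reports, "N")
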