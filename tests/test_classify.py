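"""Metrics, grid search, and validation-scheme contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiowave import classify as cl, synthetic as syn
from cardiowave.exceptions import InvalidArgumentError, InvalidFamilyError


class TestComputeMetrics:
    def test_hand_computed_binary_case(self):
        m = cl.compute_metrics(cl.ConfusionCounts.binary(tp=9, fp=1, tn=8, fn=2))
        as_metrics = m["per_class"]["AS"]
        assert as_metrics["precision"] == pytest.approx(0.9)
        assert as_metrics["recall"] == pytest.approx(9 / 11)
        assert m["accuracy"] == pytest.approx(17 / 20)

    def test_perfect_classifier(self):
        m = cl.compute_metrics(cl.ConfusionCounts.binary(tp=5, fp=0, tn=5, fn=0))
        for cls in ("AS", "NON_AS"):
            assert m["per_class"][cls] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}
        assert m["accuracy"] == 1.0

    def test_zero_denominator_convention(self, caplog):
        # no positive predictions at all: precision 0 by convention, logged
        with caplog.at_level("WARNING"):
            m = cl.compute_metrics(cl.ConfusionCounts.binary(tp=0, fp=0, tn=8, fn=2))
        assert m["per_class"]["AS"]["precision"] == 0.0
        assert m["per_class"]["AS"]["f1"] == 0.0
        assert "undefined" in caplog.text

    def test_f1_is_harmonic_mean(self):
        m = cl.compute_metrics(cl.ConfusionCounts.binary(tp=8, fp=2, tn=6, fn=4))
        p = m["per_class"]["AS"]["precision"]
        r = m["per_class"]["AS"]["recall"]
        assert m["per_class"]["AS"]["f1"] == pytest.approx(2 * p * r / (p + r))

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=1, max_size=60))
    def test_agrees_with_sklearn_recount(self, pairs):
        """Metrics from pooled confusion match an independent recount of
        the stored (truth, prediction) pairs."""
        from sklearn.metrics import accuracy_score, precision_score, recall_score

        classes = [str(k) for k in range(4)]
        truths = [classes[t] for t, _ in pairs]
        preds = [classes[p] for _, p in pairs]
        confusion = cl.ConfusionCounts.from_predictions(truths, preds, classes)
        ours = cl.compute_metrics(confusion)
        assert ours["accuracy"] == pytest.approx(accuracy_score(truths, preds))
        for cls in classes:
            sk_p = precision_score(truths, preds, labels=[cls], average="macro",
                                   zero_division=0)
            sk_r = recall_score(truths, preds, labels=[cls], average="macro",
                                zero_division=0)
            assert ours["per_class"][cls]["precision"] == pytest.approx(sk_p)
            assert ours["per_class"][cls]["recall"] == pytest.approx(sk_r)

    def test_empty_confusion_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cl.compute_metrics(cl.ConfusionCounts.binary(0, 0, 0, 0))


class TestGridSearch:
    def test_single_point_grid_is_returned(self, planted_table):
        table, _ = planted_table
        _, best, _ = cl.grid_search_fit(table, "DT", {"max_depth": [4]}, seed=0)
        assert best == {"max_depth": 4}

    def test_deterministic_in_seed(self, planted_table):
        table, _ = planted_table
        grid = {"max_depth": [2, 4], "min_samples_split": [2, 8]}
        _, a, _ = cl.grid_search_fit(table, "DT", grid, seed=9)
        _, b, _ = cl.grid_search_fit(table, "DT", grid, seed=9)
        assert a == b

    def test_xgb_separates_planted_classes(self, planted_table):
        table, _ = planted_table
        model, _, codec = cl.grid_search_fit(
            table, "XGB", cl.FAST_GRIDS["XGB"], seed=0)
        preds = codec.decode(model.predict(table.matrix))
        assert np.mean([p == t for p, t in zip(preds, table.labels)]) >= 0.99

    def test_unknown_family_rejected(self, planted_table):
        table, _ = planted_table
        with pytest.raises(InvalidFamilyError):
            cl.grid_search_fit(table, "SVM", {"C": [1]}, seed=0)

    def test_empty_grid_rejected(self, planted_table):
        table, _ = planted_table
        with pytest.raises(InvalidArgumentError):
            cl.grid_search_fit(table, "DT", {}, seed=0)


class TestLoso:
    def test_prediction_count_and_no_leak(self):
        t = syn.subject_effect_table(n_subjects_per_class=3, segments_per_subject=1, seed=0)
        report = cl.evaluate_loso(t, "DT", cl.FAST_GRIDS["DT"], seed=0)
        assert len(report.predictions) == 6
        assert report.confusion.total == 6
        assert report.extras["n_subjects"] == 6

    def test_needs_three_subjects(self):
        t = syn.subject_effect_table(n_subjects_per_class=1, segments_per_subject=4, seed=0)
        with pytest.raises(InvalidArgumentError):
            cl.evaluate_loso(t, "DT", cl.FAST_GRIDS["DT"], seed=0)

    def test_metrics_match_recount_of_stored_pairs(self):
        t = syn.subject_effect_table(n_subjects_per_class=5, segments_per_subject=4, seed=1)
        report = cl.evaluate_loso(t, "DT", cl.FAST_GRIDS["DT"], seed=1)
        recount = cl.ConfusionCounts.from_predictions(
            report.truths, report.predictions, report.confusion.classes)
        assert np.array_equal(recount.matrix, report.confusion.matrix)
        assert report.accuracy == pytest.approx(
            np.mean([t == p for t, p in zip(report.truths, report.predictions)]))

    def test_subject_shuffled_labels_give_chance_accuracy(self):
        t = syn.subject_effect_table(n_subjects_per_class=10, segments_per_subject=6,
                                     effect_size=2.0, subject_sd=0.5, seed=2)
        # reassign labels per subject, balanced, independent of content
        rng = np.random.default_rng(0)
        subjects = list(dict.fromkeys(t.subject_ids))
        new_label = dict(zip(rng.permutation(subjects),
                             ["AS", "NON_AS"] * (len(subjects) // 2)))
        shuffled = syn.subject_effect_table(n_subjects_per_class=10,
                                            segments_per_subject=6,
                                            effect_size=2.0, subject_sd=0.5, seed=2)
        shuffled.labels = [new_label[s] for s in shuffled.subject_ids]
        report = cl.evaluate_loso(shuffled, "DT", cl.FAST_GRIDS["DT"], seed=0)
        assert 0.35 <= report.accuracy <= 0.65


class TestLeaveDataOut:
    def test_split_sizes(self):
        t = syn.subject_effect_table(n_subjects_per_class=10, segments_per_subject=5, seed=0)
        report = cl.evaluate_leave_data_out(t, "DT", cl.FAST_GRIDS["DT"],
                                            ratio=0.2, seed=0)
        assert report.extras["n_test"] == 20
        assert report.confusion.total == 20

    def test_invalid_ratio_rejected(self):
        t = syn.subject_effect_table(n_subjects_per_class=3, segments_per_subject=3, seed=0)
        with pytest.raises(InvalidArgumentError):
            cl.evaluate_leave_data_out(t, "DT", ratio=1.5, seed=0)

    def test_four_class_separable_table_scores_high_f1(self, rng):
        rows, labels = [], []
        for k, label in enumerate(["AS", "AS_MI", "AS_MS", "AS_TR"]):
            x = rng.standard_normal((50, 20))
            x[:, 4 * k: 4 * k + 4] += 3.0
            rows.append(x)
            labels += [label] * 50
        t = cl.FeatureTable(np.vstack(rows), [f"F{j:03d}" for j in range(20)],
                            [f"S{i}" for i in range(200)], labels)
        report = cl.evaluate_leave_data_out(t, "RF", cl.FAST_GRIDS["RF"],
                                            ratio=0.2, seed=0)
        for cls in ("AS", "AS_MI", "AS_MS", "AS_TR"):
            assert report.per_class[cls]["f1"] >= 0.9

    def test_loso_is_harder_than_leave_data_out(self):
        """Subject random effects make segment-level splits optimistic:
        over seeds, mean LDO accuracy >= mean LOSO accuracy."""
        loso, ldo = [], []
        for seed in range(10):
            t = syn.subject_effect_table(
                n_subjects_per_class=8, segments_per_subject=6,
                effect_size=0.8, subject_sd=1.2, seed=seed)
            loso.append(cl.evaluate_loso(t, "DT", cl.FAST_GRIDS["DT"], seed=seed).accuracy)
            ldo.append(cl.evaluate_leave_data_out(
                t, "DT", cl.FAST_GRIDS["DT"], ratio=0.2, seed=seed).accuracy)
        assert np.mean(ldo) >= np.mean(loso)
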