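"""Metric formulas vs a confusion-matrix oracle; protocols for curves/sweeps."""
from collections import Counter

import numpy as np
import pytest

from aderex.evaluation import (
    distance_stratified_f1,
    learning_curve,
    macro_average,
    score,
    stratified_subsample,
    sweep,
)
from aderex.types import NONE_LABEL, RELATION_TYPES


def oracle_scores(gold, pred, labels):
    """Independent confusion-matrix computation of per-class P/R/F1."""
    out = {}
    for lab in labels:
        tp = sum(1 for g, p in zip(gold, pred) if g == p == lab)
        fp = sum(1 for g, p in zip(gold, pred) if p == lab and g != lab)
        fn = sum(1 for g, p in zip(gold, pred) if g == lab and p != lab)
        prec = 100 * tp / (tp + fp) if tp + fp else 0.0
        rec = 100 * tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[lab] = (prec, rec, f1)
    return out


class TestScore:
    def test_published_macro_recall_cells(self):
        # best neural system's per-class recalls -> overall 67.71
        assert macro_average([80, 78, 76, 69, 32, 46, 93]) == 67.71

    def test_published_macro_precision_cells(self):
        # rule-baseline per-class precisions -> overall 4.57
        assert macro_average([20, 7, 2, 1, 1, 1, 0]) == 4.57

    def test_perfect_predictions(self):
        gold = ["Dosage", "Route", NONE_LABEL, "Dosage"]
        report = score(gold, gold)
        assert report.macro_precision == report.macro_recall == report.macro_f1 == 100.0
        for s in report.per_class.values():
            assert s.f1 == 100.0

    def test_matches_confusion_matrix_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        labels = list(RELATION_TYPES) + [NONE_LABEL]
        for _ in range(40):
            n = int(rng.integers(5, 200))
            gold = [labels[i] for i in rng.integers(0, len(labels), size=n)]
            pred = [labels[i] for i in rng.integers(0, len(labels), size=n)]
            report = score(gold, pred, RELATION_TYPES)
            expected = oracle_scores(gold, pred, labels)
            for lab in labels:
                s = report.per_class[lab]
                assert s.precision == pytest.approx(expected[lab][0])
                assert s.recall == pytest.approx(expected[lab][1])
                assert s.f1 == pytest.approx(expected[lab][2])
            macro = sum(expected[lab][2] for lab in RELATION_TYPES) / len(RELATION_TYPES)
            assert report.macro_f1 == pytest.approx(macro, abs=0.005)

    def test_none_excluded_from_macro(self):
        gold = [NONE_LABEL] * 10 + ["Dosage"]
        pred = [NONE_LABEL] * 10 + ["Dosage"]
        report = score(gold, pred, ["Dosage"])
        assert report.macro_f1 == 100.0
        assert NONE_LABEL in report.per_class
        assert NONE_LABEL not in report.positive_labels

    def test_zero_denominators_score_zero(self):
        gold = ["Dosage", "Route"]
        pred = [NONE_LABEL, NONE_LABEL]
        report = score(gold, pred, ["Dosage", "Route", "Severity"])
        assert report.per_class["Severity"].precision == 0.0
        assert report.per_class["Severity"].f1 == 0.0
        assert report.macro_f1 == 0.0

    def test_tp_sum_equals_correct_positive_predictions(self):
        rng = np.random.default_rng(3)
        labels = list(RELATION_TYPES) + [NONE_LABEL]
        gold = [labels[i] for i in rng.integers(0, len(labels), size=500)]
        pred = [labels[i] for i in rng.integers(0, len(labels), size=500)]
        report = score(gold, pred, RELATION_TYPES)
        tp_sum = sum(report.per_class[lab].tp for lab in RELATION_TYPES)
        correct_pos = sum(1 for g, p in zip(gold, pred) if g == p != NONE_LABEL)
        assert tp_sum == correct_pos

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score(["A"], ["A", "B"])


class TestDistanceStratified:
    def test_single_bin_equals_global(self):
        gold = ["Dosage", NONE_LABEL, "Route", "Dosage"]
        pred = ["Dosage", "Dosage", NONE_LABEL, "Dosage"]
        dists = [1, 2, 3, 4]
        curve = distance_stratified_f1(gold, pred, dists, [10], ["Dosage", "Route"])
        global_f1 = score(gold, pred, ["Dosage", "Route"]).macro_f1
        assert curve[0].macro_f1 == global_f1

    def test_perfect_predictions_all_bins_100(self):
        gold = ["Dosage"] * 6
        dists = [0, 1, 5, 9, 15, 30]
        curve = distance_stratified_f1(gold, gold, dists, [2, 10, 40], ["Dosage"])
        for bin_score in curve:
            assert bin_score.macro_f1 == 100.0

    def test_empty_bins_flagged_not_zero(self):
        curve = distance_stratified_f1(
            ["Dosage"], ["Dosage"], [1], [5, 10, 20], ["Dosage"]
        )
        assert curve[0].macro_f1 == 100.0
        assert curve[1].macro_f1 is None and curve[1].n_gold_positive == 0

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            distance_stratified_f1([], [], [], [10, 5])


def _dummy_dataset():
    from aderex.candidates import CandidateExample

    examples = []
    for i in range(40):
        label = "Dosage" if i % 2 == 0 else "Route"
        key = (f"L{i}", f"R{i}")
        examples.append(CandidateExample("d", key[0], key[1], label, "gold", key))
        examples.append(
            CandidateExample("d", key[0], f"N{i}", NONE_LABEL, "corrupted", key)
        )
    return examples


class TestLearningCurve:
    def test_stratification_preserves_proportions(self):
        examples = _dummy_dataset()
        sub = stratified_subsample(examples, 0.5, seed=0)
        counts = Counter(ex.label for ex in sub if ex.label != NONE_LABEL)
        assert counts["Dosage"] == counts["Route"] == 10  # half of 20 each

    def test_negatives_follow_their_positives(self):
        examples = _dummy_dataset()
        sub = stratified_subsample(examples, 0.3, seed=1)
        kept_keys = {ex.source_key for ex in sub if ex.provenance == "gold"}
        for ex in sub:
            if ex.label == NONE_LABEL:
                assert ex.source_key in kept_keys

    def test_fraction_one_identity(self):
        examples = _dummy_dataset()
        assert stratified_subsample(examples, 1.0, seed=9) == examples

    def test_fraction_one_curve_point_equals_full_run(self):
        examples = _dummy_dataset()

        def trainer(train_set, seed):
            majority = Counter(
                ex.label for ex in train_set if ex.label != NONE_LABEL
            ).most_common(1)[0][0]
            return lambda test_set: [majority] * len(test_set)

        table = learning_curve(
            examples, examples, trainer, fractions=(1.0,), seeds=(0,),
            positive_labels=["Dosage", "Route"],
        )
        predict = trainer(examples, 0)
        gold = [ex.label for ex in examples]
        full = score(gold, predict(examples), ["Dosage", "Route"]).macro_f1
        assert table.iloc[0]["macro_f1"] == full

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_subsample([], 0.0, seed=0)


class TestSweep:
    def test_grid_shape_and_contents(self):
        calls = []

        def run(kr, ws):
            calls.append((kr, ws))
            return {"test_macro_f1": kr * ws}

        table = sweep([0.1, 0.5], [5, 10, 30], run)
        assert len(table) == 6
        assert len(calls) == 6
        assert set(table.columns) >= {"keep_rate", "window_size", "test_macro_f1"}

    def test_single_point_grid(self):
        table = sweep([0.5], [10], lambda kr, ws: {"test_macro_f1": 1.0})
        assert len(table) == 1
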