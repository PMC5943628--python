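"""Evaluation metrics and experimental protocols.

Scoring is macro-averaged precision/recall/F1 over the *positive* relation
types; the ``None`` class is reported per-class but never enters the macro.
Conventions: p = TP/(TP+FP), r = TP/(TP+FN), F1 = 2pr/(p+r), with 0 whenever
a denominator is 0.  Macro aggregation uses unrounded per-class values; a
separate helper recomputes an overall cell from already-printed per-class
percentages.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .candidates import CandidateExample
from .types import NONE_LABEL

log = logging.getLogger(__name__)


@dataclass
class ClassScores:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    per_class: dict[str, ClassScores]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    positive_labels: list[str]

    def to_text(self) -> str:
        rows = [f"{'Relation':<12}{'P':>8}{'R':>8}{'F1':>8}{'TP':>7}{'FP':>7}{'FN':>7}"]
        for label, s in self.per_class.items():
            rows.append(
                f"{label:<12}{s.precision:>8.2f}{s.recall:>8.2f}{s.f1:>8.2f}"
                f"{s.tp:>7}{s.fp:>7}{s.fn:>7}"
            )
        rows.append(
            f"{'Overall':<12}{self.macro_precision:>8.2f}{self.macro_recall:>8.2f}"
            f"{self.macro_f1:>8.2f}"
        )
        return "\n".join(rows)

    def to_frame(self) -> pd.DataFrame:
        data = {
            label: [s.precision, s.recall, s.f1, s.tp, s.fp, s.fn]
            for label, s in self.per_class.items()
        }
        df = pd.DataFrame(data, index=["precision", "recall", "f1", "tp", "fp", "fn"]).T
        df.loc["Overall"] = [
            self.macro_precision, self.macro_recall, self.macro_f1,
            math.nan, math.nan, math.nan,
        ]
        return df


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return 100 * p, 100 * r, 100 * f1


def score(
    gold: Sequence[str],
    predicted: Sequence[str],
    positive_labels: Iterable[str] | None = None,
) -> EvalReport:
    """Per-class and macro precision/recall/F1 from aligned label sequences.

    ``positive_labels`` fixes the macro denominator (the label schema); by
    default it is every non-None label observed in the gold sequence.
    """
    if len(gold) != len(predicted):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted")
    if positive_labels is None:
        positives = sorted({g for g in gold if g != NONE_LABEL})
    else:
        positives = list(positive_labels)
    all_labels = positives + [NONE_LABEL]
    tp: Counter[str] = Counter()
    fp: Counter[str] = Counter()
    fn: Counter[str] = Counter()
    for g, p in zip(gold, predicted):
        if g == p:
            tp[g] += 1
        else:
            fp[p] += 1
            fn[g] += 1
    per_class = {}
    for label in all_labels:
        prec, rec, f1 = _prf(tp[label], fp[label], fn[label])
        per_class[label] = ClassScores(tp[label], fp[label], fn[label], prec, rec, f1)
    macro_p = sum(per_class[lab].precision for lab in positives) / len(positives) if positives else 0.0
    macro_r = sum(per_class[lab].recall for lab in positives) / len(positives) if positives else 0.0
    macro_f = sum(per_class[lab].f1 for lab in positives) / len(positives) if positives else 0.0
    return EvalReport(
        per_class=per_class,
        macro_precision=round(macro_p, 2),
        macro_recall=round(macro_r, 2),
        macro_f1=round(macro_f, 2),
        positive_labels=positives,
    )


def macro_average(per_class_values: Sequence[float], decimals: int = 2) -> float:
    """Unweighted mean of printed per-class metric cells.

    Recomputes an "Overall" table cell from the per-class percentages of a
    published results table (rounded to the printed precision).
    """
    if not per_class_values:
        raise ValueError("no values to average")
    return round(sum(per_class_values) / len(per_class_values), decimals)


@dataclass
class DistanceBinScore:
    lower: float
    upper: float
    n_examples: int
    n_gold_positive: int
    macro_f1: float | None  # None when the bin has no gold positives


def distance_stratified_f1(
    gold: Sequence[str],
    predicted: Sequence[str],
    distances: Sequence[int],
    bin_edges: Sequence[float],
    positive_labels: Iterable[str] | None = None,
) -> list[DistanceBinScore]:
    """Macro-F1 within consecutive token-distance bins ``(e_i, e_{i+1}]``.

    The first bin includes distance 0.  Bins without gold positives are
    flagged (``macro_f1 = None``) rather than scored 0.
    """
    if not (len(gold) == len(predicted) == len(distances)):
        raise ValueError("gold, predicted and distances must be aligned")
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError(f"bin edges must be strictly increasing: {edges}")
    out = []
    lower = -1.0
    for upper in edges:
        idx = [i for i, d in enumerate(distances) if lower < d <= upper]
        g = [gold[i] for i in idx]
        p = [predicted[i] for i in idx]
        n_pos = sum(1 for x in g if x != NONE_LABEL)
        f1 = score(g, p, positive_labels).macro_f1 if n_pos else None
        out.append(
            DistanceBinScore(
                lower=lower if lower >= 0 else 0.0,
                upper=upper, n_examples=len(idx), n_gold_positive=n_pos, macro_f1=f1,
            )
        )
        lower = upper
    return out


Trainer = Callable[[list[CandidateExample], int], Callable[[list[CandidateExample]], list[str]]]


def stratified_subsample(
    examples: list[CandidateExample], fraction: float, seed: int
) -> list[CandidateExample]:
    """Per-relation-type subsample of positives, with their derived negatives.

    Preserves label proportions within one example per class; negatives
    follow their source gold relation so the negative:positive structure of
    the training set is retained.
    """
    import numpy as np

    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(examples)
    rng = np.random.default_rng(seed)
    positives = [ex for ex in examples if ex.label != NONE_LABEL]
    negatives = [ex for ex in examples if ex.label == NONE_LABEL]
    by_type: dict[str, list[CandidateExample]] = {}
    for ex in positives:
        by_type.setdefault(ex.label, []).append(ex)
    kept_keys: set[tuple[str, tuple[str, str]]] = set()
    kept: list[CandidateExample] = []
    for label in sorted(by_type):
        group = by_type[label]
        n_keep = int(round(fraction * len(group)))
        if n_keep == 0:
            log.warning("fraction %.2f empties class %s; dropping it", fraction, label)
            continue
        chosen = rng.choice(len(group), size=n_keep, replace=False)
        for i in sorted(chosen):
            kept.append(group[i])
            kept_keys.add((group[i].doc_id, group[i].source_key))
    kept_negatives = [
        ex for ex in negatives if (ex.doc_id, ex.source_key) in kept_keys
    ]
    order = {id(ex): i for i, ex in enumerate(examples)}
    return sorted(kept + kept_negatives, key=lambda ex: order[id(ex)])


def learning_curve(
    train_examples: list[CandidateExample],
    test_examples: list[CandidateExample],
    trainer: Trainer,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    seeds: Sequence[int] = (0,),
    positive_labels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test macro-F1 as a function of the stratified training fraction."""
    gold = [ex.label for ex in test_examples]
    rows = []
    for fraction in fractions:
        for seed in seeds:
            subset = stratified_subsample(train_examples, fraction, seed)
            predict = trainer(subset, seed)
            report = score(gold, predict(test_examples), positive_labels)
            rows.append(
                {
                    "fraction": fraction,
                    "seed": seed,
                    "n_train": len(subset),
                    "macro_f1": report.macro_f1,
                }
            )
    return pd.DataFrame(rows)


def sweep(
    keep_rates: Sequence[float],
    window_sizes: Sequence[int],
    run: Callable[[float, int], dict[str, float]],
) -> pd.DataFrame:
    """One train/eval run per (keep rate, window size) grid point."""
    rows = []
    for kr in keep_rates:
        for ws in window_sizes:
            result = run(kr, ws)
            rows.append({"keep_rate": kr, "window_size": ws, **result})
    return pd.DataFrame(rows)
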