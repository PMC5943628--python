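"""Distance-bin rule-induction baseline.

Training computes the average token distance of gold pairs per relation
type; the types, sorted by those averages, define consecutive distance bins
``(mean_{i-1}, mean_i]`` (the first bin closed at 0 so that adjacent
attribute pairs — the most canonical positives — are classifiable).  A pair
whose distance falls outside every bin is ``None``.  The classifier is a
pure function of token distance.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

from .candidates import CandidateExample
from .types import NONE_LABEL, AnnotatedDocument, token_distance

log = logging.getLogger(__name__)


@dataclass
class DistanceBinModel:
    """Ordered ``(upper_bound, label)`` bins over token distance."""

    bins: list[tuple[float, str]]  # strictly increasing upper bounds

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.bins]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"bin bounds not strictly increasing: {bounds}")

    def predict_distance(self, distance: float) -> str:
        """Label for a token distance; 0 falls in the first bin."""
        if distance < 0:
            raise ValueError("distance must be >= 0")
        lower = -1.0  # first bin includes 0
        for bound, label in self.bins:
            if lower < distance <= bound:
                return label
            lower = bound
        return NONE_LABEL

    def to_json(self) -> str:
        return json.dumps({"bins": [[b, lab] for b, lab in self.bins]}, indent=2)

    @classmethod
    def from_json(cls, content: str) -> "DistanceBinModel":
        data = json.loads(content)
        return cls(bins=[(float(b), str(lab)) for b, lab in data["bins"]])


def fit_distance_bins(
    examples: list[CandidateExample], docs: dict[str, AnnotatedDocument]
) -> DistanceBinModel:
    """Induce bins from the mean gold-pair distance of each relation type.

    Only gold positives enter the fit.  Tied means are resolved in favor of
    the type with more training instances; the losing type's bound is nudged
    up by an epsilon, leaving it a formally present but integer-empty bin.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ex in examples:
        if ex.provenance != "gold" or ex.label == NONE_LABEL:
            continue
        doc = docs[ex.doc_id]
        d = token_distance(doc, doc.mention(ex.left_id), doc.mention(ex.right_id))
        sums[ex.label] = sums.get(ex.label, 0.0) + d
        counts[ex.label] = counts.get(ex.label, 0) + 1
    if not counts:
        raise ValueError("no gold positive examples to fit on")
    means = {t: sums[t] / counts[t] for t in counts}
    # sort by mean ascending; ties → larger class first (keeps the true bound)
    ordered = sorted(means, key=lambda t: (means[t], -counts[t], t))
    bins: list[tuple[float, str]] = []
    prev = -1.0
    for t in ordered:
        bound = means[t]
        if bound <= prev:
            log.warning("tied/duplicate mean for %s; nudging bound above %.6g", t, prev)
            bound = prev + 1e-9
        bins.append((bound, t))
        prev = bound
    return DistanceBinModel(bins=bins)


def predict_rule(
    model: DistanceBinModel,
    doc: AnnotatedDocument,
    example: CandidateExample,
) -> str:
    d = token_distance(doc, doc.mention(example.left_id), doc.mention(example.right_id))
    return model.predict_distance(d)
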