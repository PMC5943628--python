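"""Classification examples: gold positives plus corruption-generated negatives.

Negative (``None``) relations are produced by replacing one mention of a true
relation with another mention from the same document, under the single
constraint that the corrupted pair must not itself be a true relation.
Down-sampling with a keep rate is applied to the *training* negatives only;
development and test sets are never down-sampled.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .types import NONE_LABEL, AnnotatedDocument

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateExample:
    """One entity pair in its document, labeled with a relation type or None.

    ``source_key`` identifies the gold relation a corrupted example was
    derived from (its own pair for gold examples), which lets stratified
    subsampling keep negatives with their originating positives.
    """

    doc_id: str
    left_id: str
    right_id: str
    label: str
    provenance: str  # "gold" | "corrupted"
    source_key: tuple[str, str] = ("", "")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.left_id, self.right_id})


def corpus_index(docs: list[AnnotatedDocument]) -> dict[str, AnnotatedDocument]:
    return {d.doc_id: d for d in docs}


def gold_examples(docs: list[AnnotatedDocument]) -> list[CandidateExample]:
    out = []
    for doc in docs:
        for r in doc.relations:
            out.append(
                CandidateExample(
                    doc_id=doc.doc_id,
                    left_id=r.left_id,
                    right_id=r.right_id,
                    label=r.label,
                    provenance="gold",
                    source_key=(r.left_id, r.right_id),
                )
            )
    return out


def _overlap(doc: AnnotatedDocument, a: str, b: str) -> bool:
    ma, mb = doc.mention(a), doc.mention(b)
    return not (ma.last < mb.first or mb.last < ma.first)


#: Default corruption multiplicity: up to 2 x 45 negatives per gold relation,
#: i.e. roughly a 90:1 negative:positive ratio before down-sampling.
DEFAULT_CORRUPTIONS_PER_SIDE = 45


def generate_negatives(
    docs: list[AnnotatedDocument],
    corruptions_per_side: int = DEFAULT_CORRUPTIONS_PER_SIDE,
    seed: int = 0,
) -> list[CandidateExample]:
    """Corrupt each gold relation by swapping one mention for another.

    For each gold relation, up to ``corruptions_per_side`` replacements of
    each mention with another mention of the same document (OtherSS and
    overlapping mentions excluded), sampled uniformly without replacement,
    rejecting any pair that is a gold positive or an already-emitted
    negative.  Deterministic under ``seed``.
    """
    if corruptions_per_side < 0:
        raise ValueError("corruptions_per_side must be >= 0")
    rng = np.random.default_rng(seed)
    negatives: list[CandidateExample] = []
    for doc in docs:
        eligible = [m.id for m in doc.mentions if m.etype != "OtherSS"]
        if len(eligible) < 3 and doc.relations:
            log.info("document %s has < 3 eligible mentions: no negatives", doc.doc_id)
            continue
        gold_pairs = {frozenset({r.left_id, r.right_id}) for r in doc.relations}
        emitted: set[frozenset[str]] = set()
        for r in doc.relations:
            for kept, replaced in ((r.left_id, r.right_id), (r.right_id, r.left_id)):
                pool = [m for m in eligible if m not in (kept, replaced)]
                rng.shuffle(pool)
                made = 0
                for cand in pool:
                    if made >= corruptions_per_side:
                        break
                    pair = frozenset({kept, cand})
                    if pair in gold_pairs or pair in emitted or _overlap(doc, kept, cand):
                        continue
                    left, right = sorted(
                        (kept, cand), key=lambda mid: doc.mention(mid).first
                    )
                    negatives.append(
                        CandidateExample(
                            doc_id=doc.doc_id,
                            left_id=left,
                            right_id=right,
                            label=NONE_LABEL,
                            provenance="corrupted",
                            source_key=(r.left_id, r.right_id),
                        )
                    )
                    emitted.add(pair)
                    made += 1
    return negatives


def downsample(
    negatives: list[CandidateExample], keep_rate: float, seed: int
) -> list[CandidateExample]:
    """Retain each negative independently with probability ``keep_rate``."""
    if not 0.0 <= keep_rate <= 1.0:
        raise ValueError(f"keep_rate must be in [0, 1], got {keep_rate}")
    if keep_rate == 1.0:
        return list(negatives)
    rng = np.random.default_rng(seed)
    draws = rng.random(len(negatives))
    return [ex for ex, u in zip(negatives, draws) if u < keep_rate]


def build_dataset(
    docs: list[AnnotatedDocument],
    negatives: list[CandidateExample],
    seed: int = 0,
) -> tuple[list[CandidateExample], dict[str, int]]:
    """Positives plus negatives, deduplicated and deterministically shuffled.

    Returns the example list and a per-label count histogram.
    """
    doc_ids = {d.doc_id for d in docs}
    for ex in negatives:
        if ex.doc_id not in doc_ids:
            raise ValueError(f"negative references unknown document {ex.doc_id}")
    examples = gold_examples(docs) + list(negatives)
    seen: set[tuple[str, frozenset[str], str]] = set()
    unique: list[CandidateExample] = []
    for ex in examples:
        key = (ex.doc_id, ex.pair, ex.label)
        if key in seen:
            log.warning("duplicate example %s dropped", key)
            continue
        seen.add(key)
        unique.append(ex)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    shuffled = [unique[i] for i in order]
    return shuffled, dict(Counter(ex.label for ex in shuffled))


def serialize_dataset(examples: list[CandidateExample]) -> str:
    """Delimited text: doc_id, left_id, right_id, label, provenance."""
    lines = ["doc_id\tleft_id\tright_id\tlabel\tprovenance"]
    for ex in examples:
        lines.append(f"{ex.doc_id}\t{ex.left_id}\t{ex.right_id}\t{ex.label}\t{ex.provenance}")
    return "\n".join(lines) + "\n"


def deserialize_dataset(content: str) -> list[CandidateExample]:
    lines = content.strip().splitlines()
    out = []
    for line in lines[1:]:
        doc_id, left, right, label, prov = line.split("\t")
        out.append(
            CandidateExample(
                doc_id=doc_id, left_id=left, right_id=right, label=label, provenance=prov
            )
        )
    return out
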