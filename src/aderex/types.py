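"""Core domain types for document-level clinical relation extraction.

The task: given an annotated clinical note, classify each entity-mention
pair ``(e_l, e_r)`` into one of seven medication/ADE relation types or
``None``.  Relations may cross sentence boundaries, so every distance is
measured in document-wide token positions, never within a sentence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: The nine entity types: eight relation-bearing ones plus "other signs and
#: symptoms" (OtherSS), which never participates in a relation.
ENTITY_TYPES = (
    "Medication",
    "Indication",
    "ADE",
    "Severity",
    "Dosage",
    "Route",
    "Frequency",
    "Duration",
    "OtherSS",
)

#: The seven positive relation labels.
RELATION_TYPES = (
    "Dosage",
    "Route",
    "Frequency",
    "Duration",
    "Indication",
    "Adverse",
    "Severity",
)

NONE_LABEL = "None"

#: Unordered entity-type pair licensed by each relation label.  A positive
#: relation must connect exactly these two types (in either document order).
RELATION_SCHEMA: dict[str, frozenset[str]] = {
    "Dosage": frozenset({"Medication", "Dosage"}),
    "Route": frozenset({"Medication", "Route"}),
    "Frequency": frozenset({"Medication", "Frequency"}),
    "Duration": frozenset({"Medication", "Duration"}),
    "Indication": frozenset({"Medication", "Indication"}),
    "Adverse": frozenset({"Medication", "ADE"}),
    "Severity": frozenset({"Severity", "ADE"}),
}


class DocumentError(ValueError):
    """An AnnotatedDocument (or its construction input) violates an invariant."""


@dataclass(frozen=True)
class Token:
    surface: str
    char_start: int
    char_end: int  # exclusive
    sentence_index: int
    token_index: int  # document-wide position

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise DocumentError(
                f"token {self.surface!r}: char_start {self.char_start} >= char_end {self.char_end}"
            )


@dataclass(frozen=True)
class EntityMention:
    id: str
    etype: str
    token_span: tuple[int, int]  # inclusive [first, last] document token indices
    text: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise DocumentError(f"mention {self.id}: unknown entity type {self.etype!r}")
        first, last = self.token_span
        if first > last:
            raise DocumentError(f"mention {self.id}: token span {self.token_span} inverted")

    @property
    def first(self) -> int:
        return self.token_span[0]

    @property
    def last(self) -> int:
        return self.token_span[1]


@dataclass(frozen=True)
class RelationInstance:
    """A labeled mention pair; ``left`` precedes ``right`` in document order."""

    left_id: str
    right_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in RELATION_TYPES and self.label != NONE_LABEL:
            raise DocumentError(f"unknown relation label {self.label!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.left_id, self.right_id})


@dataclass
class AnnotatedDocument:
    doc_id: str
    raw_text: str
    tokens: list[Token]
    mentions: list[EntityMention]
    relations: list[RelationInstance]
    _mention_index: dict[str, EntityMention] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._mention_index = {m.id: m for m in self.mentions}
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens):
            if tok.token_index != i:
                raise DocumentError(f"{self.doc_id}: token_index {tok.token_index} at position {i}")
        for i in range(1, n):
            if self.tokens[i].sentence_index < self.tokens[i - 1].sentence_index:
                raise DocumentError(f"{self.doc_id}: sentence_index decreases at token {i}")
        if len(self._mention_index) != len(self.mentions):
            raise DocumentError(f"{self.doc_id}: duplicate mention ids")
        for m in self.mentions:
            if m.last >= n:
                raise DocumentError(f"{self.doc_id}: mention {m.id} span {m.token_span} outside document")
        seen: set[tuple[frozenset[str], str]] = set()
        for r in self.relations:
            for mid in (r.left_id, r.right_id):
                if mid not in self._mention_index:
                    raise DocumentError(f"{self.doc_id}: relation references missing mention {mid}")
            left = self._mention_index[r.left_id]
            right = self._mention_index[r.right_id]
            if left.first > right.first:
                raise DocumentError(
                    f"{self.doc_id}: relation ({r.left_id},{r.right_id}) not in document order"
                )
            if r.label != NONE_LABEL:
                if "OtherSS" in (left.etype, right.etype):
                    raise DocumentError(f"{self.doc_id}: OtherSS mention in positive relation")
                allowed = RELATION_SCHEMA[r.label]
                if frozenset({left.etype, right.etype}) != allowed:
                    raise DocumentError(
                        f"{self.doc_id}: {r.label} relation connects "
                        f"{left.etype}/{right.etype}, expected {set(allowed)}"
                    )
                key = (r.pair, r.label)
                if key in seen:
                    raise DocumentError(f"{self.doc_id}: duplicate positive relation {key}")
                seen.add(key)

    def mention(self, mention_id: str) -> EntityMention:
        return self._mention_index[mention_id]

    @property
    def n_sentences(self) -> int:
        return (self.tokens[-1].sentence_index + 1) if self.tokens else 0


def _ordered(a: EntityMention, b: EntityMention) -> tuple[EntityMention, EntityMention]:
    if a.first <= b.first and a.last < b.first:
        return a, b
    if b.first <= a.first and b.last < a.first:
        return b, a
    raise DocumentError(f"mentions {a.id} and {b.id} overlap: spans {a.token_span}, {b.token_span}")


def token_distance(doc: AnnotatedDocument, a: EntityMention, b: EntityMention) -> int:
    """Number of tokens strictly between two non-overlapping mentions.

    Adjacent mentions are at distance 0 (an attribute right next to its drug
    name), so this is an exclusive count, symmetric in its arguments.
    """
    first, second = _ordered(a, b)
    return second.first - first.last - 1


def mentions_between(doc: AnnotatedDocument, a: EntityMention, b: EntityMention) -> int:
    """Count other mentions whose spans lie entirely between the pair."""
    first, second = _ordered(a, b)
    lo, hi = first.last, second.first
    count = 0
    for m in doc.mentions:
        if m.id in (a.id, b.id):
            continue
        if m.first > lo and m.last < hi:
            count += 1
    return count


def intersentential(doc: AnnotatedDocument, a: EntityMention, b: EntityMention) -> bool:
    """True when the two mentions occur in different sentences."""
    sa = doc.tokens[a.first].sentence_index
    sb = doc.tokens[b.first].sentence_index
    return sa != sb
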