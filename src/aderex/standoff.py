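"""Tokenization and BRAT-style standoff annotation I/O.

A document is a pair of files: the raw note text and an annotation file with
``T`` lines (entity mentions, 0-based end-exclusive character offsets) and
``R`` lines (binary relations between mention ids)::

    T1\tMedication 13 22\tAlbuterol
    R1\tDosage Arg1:T1 Arg2:T2

The tokenizer is deliberately simple (whitespace split, leading/trailing
punctuation peeled off, sentence break after ``.!?``): synthetic corpora are
emitted pre-tokenized, so nothing downstream depends on its finer points.
"""
from __future__ import annotations

import string
from pathlib import Path

from .types import (
    ENTITY_TYPES,
    RELATION_TYPES,
    AnnotatedDocument,
    DocumentError,
    EntityMention,
    RelationInstance,
    Token,
)

_PUNCT = set(string.punctuation)
_SENT_FINAL = {".", "!", "?"}


class StandoffParseError(ValueError):
    """A standoff annotation line could not be interpreted."""


def tokenize(raw_text: str) -> list[Token]:
    """Split text into tokens covering every non-whitespace character.

    Punctuation at the edge of a whitespace-delimited chunk becomes its own
    token; internal punctuation (``q4-6h``) is kept.  The sentence index is
    incremented after sentence-final punctuation followed by whitespace.
    """
    if not raw_text or raw_text.strip() == "":
        raise DocumentError("empty or whitespace-only document")

    tokens: list[Token] = []
    sentence = 0
    pending_break = False
    i, n = 0, len(raw_text)
    while i < n:
        if raw_text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not raw_text[j].isspace():
            j += 1
        # split the chunk [i, j) into leading punct / core / trailing punct
        a, b = i, j
        lead: list[tuple[int, int]] = []
        trail: list[tuple[int, int]] = []
        while a < b and raw_text[a] in _PUNCT:
            lead.append((a, a + 1))
            a += 1
        while b > a and raw_text[b - 1] in _PUNCT:
            trail.append((b - 1, b))
            b -= 1
        spans = lead + ([(a, b)] if a < b else []) + list(reversed(trail))
        for s, e in spans:
            if pending_break:
                sentence += 1
                pending_break = False
            tokens.append(
                Token(
                    surface=raw_text[s:e],
                    char_start=s,
                    char_end=e,
                    sentence_index=sentence,
                    token_index=len(tokens),
                )
            )
        if tokens and tokens[-1].surface in _SENT_FINAL:
            pending_break = True
        i = j
    return tokens


def _align_span(tokens: list[Token], start: int, end: int, line: str) -> tuple[int, int]:
    covered = [t for t in tokens if t.char_start >= start and t.char_end <= end]
    if not covered or covered[0].char_start != start or covered[-1].char_end != end:
        raise StandoffParseError(f"offsets not aligned to token boundaries: {line!r}")
    return covered[0].token_index, covered[-1].token_index


def read_standoff(text_content: str, ann_content: str, doc_id: str = "doc") -> AnnotatedDocument:
    """Parse a (.txt, .ann) pair into an :class:`AnnotatedDocument`."""
    tokens = tokenize(text_content)
    mentions: list[EntityMention] = []
    mention_ids: set[str] = set()
    relation_lines: list[str] = []

    for raw_line in ann_content.splitlines():
        line = raw_line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("T"):
            parts = line.split("\t")
            if len(parts) < 3:
                raise StandoffParseError(f"malformed T line: {line!r}")
            tid, header, text = parts[0], parts[1], parts[2]
            try:
                etype, s_str, e_str = header.split(" ")
                start, end = int(s_str), int(e_str)
            except ValueError as exc:
                raise StandoffParseError(f"malformed T header: {line!r}") from exc
            if etype not in ENTITY_TYPES:
                raise StandoffParseError(f"unknown entity type {etype!r}: {line!r}")
            if not (0 <= start < end <= len(text_content)):
                raise StandoffParseError(f"offsets outside text: {line!r}")
            if text_content[start:end] != text:
                raise StandoffParseError(f"mention text does not match offsets: {line!r}")
            first, last = _align_span(tokens, start, end, line)
            mentions.append(EntityMention(id=tid, etype=etype, token_span=(first, last), text=text))
            mention_ids.add(tid)
        elif line.startswith("R"):
            relation_lines.append(line)
        else:
            raise StandoffParseError(f"unrecognized annotation line: {line!r}")

    index = {m.id: m for m in mentions}
    relations: list[RelationInstance] = []
    for line in relation_lines:
        parts = line.split("\t")
        if len(parts) < 2:
            raise StandoffParseError(f"malformed R line: {line!r}")
        try:
            label, arg1, arg2 = parts[1].split(" ")
            a1 = arg1.split(":", 1)[1]
            a2 = arg2.split(":", 1)[1]
        except (ValueError, IndexError) as exc:
            raise StandoffParseError(f"malformed R line: {line!r}") from exc
        if label not in RELATION_TYPES:
            raise StandoffParseError(f"unknown relation type {label!r}: {line!r}")
        for mid in (a1, a2):
            if mid not in index:
                raise StandoffParseError(f"dangling relation argument {mid!r}: {line!r}")
        # left/right assigned by document order; the label carries the semantics
        left, right = (a1, a2) if index[a1].first <= index[a2].first else (a2, a1)
        relations.append(RelationInstance(left_id=left, right_id=right, label=label))

    return AnnotatedDocument(
        doc_id=doc_id, raw_text=text_content, tokens=tokens, mentions=mentions, relations=relations
    )


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize a document; inverse of :func:`read_standoff`."""
    lines: list[str] = []
    for m in doc.mentions:
        if "\n" in m.text:
            raise DocumentError(f"{doc.doc_id}: mention {m.id} text contains a newline")
        start = doc.tokens[m.first].char_start
        end = doc.tokens[m.last].char_end
        if doc.raw_text[start:end] != m.text:
            raise DocumentError(f"{doc.doc_id}: mention {m.id} text disagrees with its span")
        lines.append(f"{m.id}\t{m.etype} {start} {end}\t{m.text}")
    for i, r in enumerate(doc.relations, start=1):
        lines.append(f"R{i}\t{r.label} Arg1:{r.left_id} Arg2:{r.right_id}")
    ann = "\n".join(lines) + ("\n" if lines else "")
    return doc.raw_text, ann


def save_corpus(docs: list[AnnotatedDocument], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        text, ann = write_standoff(doc)
        (directory / f"{doc.doc_id}.txt").write_text(text)
        (directory / f"{doc.doc_id}.ann").write_text(ann)


def load_corpus(directory: str | Path) -> list[AnnotatedDocument]:
    directory = Path(directory)
    docs = []
    for txt in sorted(directory.glob("*.txt")):
        ann = txt.with_suffix(".ann")
        docs.append(
            read_standoff(
                txt.read_text(),
                ann.read_text() if ann.exists() else "",
                doc_id=txt.stem,
            )
        )
    return docs
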