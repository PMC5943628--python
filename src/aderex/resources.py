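"""External lexical resources: word embeddings, Brown-cluster paths, semantic tags.

Training these at corpus scale is out of scope; they are loaded from the
standard text file formats (word2vec text, Percy-Liang-style paths file,
TSV dictionary) or synthesized by :mod:`aderex.synthetic`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

log = logging.getLogger(__name__)


class ResourceFormatError(ValueError):
    """A resource file does not follow its declared format."""


@dataclass
class EmbeddingTable:
    """Dense word vectors; unknown words fall back to ``unk_vector``."""

    dimension: int
    entries: dict[str, np.ndarray]
    unk_vector: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unk_vector is None:
            self.unk_vector = np.zeros(self.dimension)
        for w, v in self.entries.items():
            if v.shape != (self.dimension,):
                raise ResourceFormatError(
                    f"vector for {w!r} has length {v.shape}, expected {self.dimension}"
                )

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def lookup(self, word: str) -> np.ndarray:
        return self.entries.get(word, self.unk_vector)

    @property
    def vocabulary(self) -> list[str]:
        return list(self.entries)


def load_embeddings(content: str) -> EmbeddingTable:
    """Parse word2vec text format: header ``V D`` then ``word f1 ... fD`` lines."""
    lines = content.splitlines()
    if not lines:
        raise ResourceFormatError("empty embedding file")
    try:
        n_words, dim = (int(x) for x in lines[0].split())
    except ValueError as exc:
        raise ResourceFormatError(f"malformed header: {lines[0]!r}") from exc
    entries: dict[str, np.ndarray] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.rstrip().split(" ")
        word, values = parts[0], parts[1:]
        if len(values) != dim:
            raise ResourceFormatError(
                f"word {word!r} has {len(values)} components, expected {dim}"
            )
        if word in entries:
            log.warning("duplicate embedding for %r: last occurrence wins", word)
        entries[word] = np.array([float(v) for v in values])
    if len(entries) != n_words:
        log.warning("header declared %d words, parsed %d", n_words, len(entries))
    return EmbeddingTable(dimension=dim, entries=entries)


def write_embeddings(table: EmbeddingTable) -> str:
    lines = [f"{len(table.entries)} {table.dimension}"]
    for word, vec in table.entries.items():
        lines.append(word + " " + " ".join(repr(float(x)) for x in vec))
    return "\n".join(lines) + "\n"


@dataclass
class BrownPaths:
    """Hierarchical word clusters as bit-string paths; prefixes = coarse classes."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for w, bits in self.entries.items():
            if not bits or set(bits) - {"0", "1"}:
                raise ResourceFormatError(f"invalid bit-string {bits!r} for {w!r}")

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def path(self, word: str) -> str | None:
        return self.entries.get(word)


def load_brown_paths(content: str) -> BrownPaths:
    """Parse a paths file: ``bit-string TAB word TAB count`` per line."""
    entries: dict[str, str] = {}
    for line in content.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ResourceFormatError(f"malformed paths line: {line!r}")
        bits, word = parts[0], parts[1]
        if word in entries:
            log.warning("duplicate Brown path for %r: last occurrence wins", word)
        entries[word] = bits
    return BrownPaths(entries=entries)


class SemanticTagger(Protocol):
    """Maps a word to a set of semantic-type strings.

    Stands in for a concept normalizer (UMLS-style); implementations may wrap
    anything from a dictionary file to a full terminology server.
    """

    def tags(self, word: str) -> frozenset[str]: ...


@dataclass
class DictionarySemanticTagger:
    """Dictionary-backed tagger; loaded from TSV ``word TAB type[,type...]``."""

    mapping: dict[str, frozenset[str]]

    def tags(self, word: str) -> frozenset[str]:
        return self.mapping.get(word.lower(), frozenset())

    @classmethod
    def from_tsv(cls, content: str) -> "DictionarySemanticTagger":
        mapping: dict[str, frozenset[str]] = {}
        for line in content.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ResourceFormatError(f"malformed tagger line: {line!r}")
            mapping[parts[0].lower()] = frozenset(parts[1].split(","))
        return cls(mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "DictionarySemanticTagger":
        return cls.from_tsv(Path(path).read_text())


@dataclass
class NullSemanticTagger:
    def tags(self, word: str) -> frozenset[str]:  # noqa: ARG002
        return frozenset()
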