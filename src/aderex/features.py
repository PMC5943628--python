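"""Sparse feature extraction for the linear-SVM relation classifier.

Five namespaced feature families per candidate pair:

* ``doc:`` document-level entity / entity-type frequencies,
* ``rel:`` token distance, mention count between the pair, TF-IDF-weighted
  word 1/2/3-grams between the pair and in a context window around each
  mention,
* ``ent:`` one-hot entity types and TF-IDF-weighted character 2/3-grams of
  the mention strings,
* ``sem:`` semantic-type tags of the mentions and their context from a
  pluggable tagger,
* ``wr:`` word representations — Brown-path prefixes and word-vector-class
  ids of context tokens, plus the mean embedding of each mention's tokens
  as dense dimensions.

TF-IDF statistics (vocabulary and document frequencies) are fitted on the
training documents only and frozen; terms unseen in training are dropped at
apply time, so development/test content can never alter the feature space.
"""
from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateExample
from .resources import BrownPaths, EmbeddingTable, NullSemanticTagger, SemanticTagger
from .types import AnnotatedDocument, mentions_between, token_distance

log = logging.getLogger(__name__)

DEFAULT_BROWN_PREFIX_LENGTHS = (4, 6, 10, 20)


def _word_ngrams(tokens: list[str], orders: tuple[int, ...] = (1, 2, 3)) -> list[str]:
    out = []
    for n in orders:
        for i in range(len(tokens) - n + 1):
            out.append("_".join(tokens[i : i + n]))
    return out


def _char_ngrams(text: str, orders: tuple[int, ...] = (2, 3)) -> list[str]:
    out = []
    for n in orders:
        for i in range(len(text) - n + 1):
            out.append(text[i : i + n])
    return out


@dataclass
class TfidfStats:
    """Document frequencies fitted on the training split; idf = ln(N/df)."""

    n_docs: int
    word_df: dict[str, int]
    char_df: dict[str, int]

    def word_idf(self, term: str) -> float | None:
        df = self.word_df.get(term)
        return math.log(self.n_docs / df) if df else None

    def char_idf(self, gram: str) -> float | None:
        df = self.char_df.get(gram)
        return math.log(self.n_docs / df) if df else None

    def to_json(self) -> str:
        return json.dumps(
            {"n_docs": self.n_docs, "word_df": self.word_df, "char_df": self.char_df}
        )

    @classmethod
    def from_json(cls, content: str) -> "TfidfStats":
        d = json.loads(content)
        return cls(n_docs=d["n_docs"], word_df=d["word_df"], char_df=d["char_df"])


def fit_tfidf(train_docs: list[AnnotatedDocument]) -> TfidfStats:
    """Fit word- and character-n-gram document frequencies on training docs."""
    if not train_docs:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    word_df: Counter[str] = Counter()
    char_df: Counter[str] = Counter()
    for doc in train_docs:
        surfaces = [t.surface.lower() for t in doc.tokens]
        word_df.update(set(_word_ngrams(surfaces)))
        grams: set[str] = set()
        for m in doc.mentions:
            grams.update(_char_ngrams(m.text.lower()))
        char_df.update(grams)
    return TfidfStats(n_docs=len(train_docs), word_df=dict(word_df), char_df=dict(char_df))


def compute_wvc(embeddings: EmbeddingTable, k: int = 300, seed: int = 0) -> dict[str, int]:
    """Word Vector Classes: k-means cluster id for every embedded word."""
    from sklearn.cluster import KMeans

    words = embeddings.vocabulary
    if not words:
        raise ValueError("empty embedding table")
    if len(words) < k:
        log.warning("vocabulary size %d < k=%d; reducing k", len(words), k)
        k = len(words)
    matrix = np.stack([embeddings.entries[w] for w in words])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(matrix)
    return {w: int(c) for w, c in zip(words, labels)}


def brown_prefixes(
    word: str, paths: BrownPaths, lengths: tuple[int, ...] = DEFAULT_BROWN_PREFIX_LENGTHS
) -> set[str]:
    """Bit-string prefixes of the word's cluster path at the requested lengths."""
    bits = paths.path(word)
    if bits is None:
        return set()
    return {bits[:n] for n in lengths}


@dataclass
class FeatureResources:
    """Fitted resources shared by all feature extractions of one experiment."""

    tfidf: TfidfStats
    embeddings: EmbeddingTable | None = None
    brown: BrownPaths | None = None
    wvc: dict[str, int] | None = None
    tagger: SemanticTagger = field(default_factory=NullSemanticTagger)
    window: int = 10


def _context_tokens(doc: AnnotatedDocument, first: int, last: int, window: int) -> list[str]:
    lo = max(0, first - window)
    left = [t.surface.lower() for t in doc.tokens[lo:first]]
    right = [t.surface.lower() for t in doc.tokens[last + 1 : last + 1 + window]]
    return left + right


def extract_features(
    example: CandidateExample,
    doc: AnnotatedDocument,
    resources: FeatureResources,
    window: int | None = None,
) -> dict[str, float]:
    """Sparse feature map for one candidate pair (no zero-valued entries)."""
    if resources.tfidf is None:
        raise ValueError("resources not fitted")
    w = resources.window if window is None else window
    left = doc.mention(example.left_id)
    right = doc.mention(example.right_id)
    feats: dict[str, float] = {}

    def put(key: str, value: float) -> None:
        if value:
            feats[key] = feats.get(key, 0.0) + value

    # document-level: frequency of each pair entity's surface and type
    surface_counts = Counter(m.text.lower() for m in doc.mentions)
    type_counts = Counter(m.etype for m in doc.mentions)
    put("doc:freq_surf_l", surface_counts[left.text.lower()])
    put("doc:freq_surf_r", surface_counts[right.text.lower()])
    put("doc:freq_type_l", type_counts[left.etype])
    put("doc:freq_type_r", type_counts[right.etype])

    # relation-specific numerics
    put("rel:distance", token_distance(doc, left, right))
    put("rel:between", mentions_between(doc, left, right))

    # word n-grams between the pair, TF-IDF weighted
    lo_m, hi_m = (left, right) if left.first <= right.first else (right, left)
    between = [t.surface.lower() for t in doc.tokens[lo_m.last + 1 : hi_m.first]]
    for term, tf in Counter(_word_ngrams(between)).items():
        idf = resources.tfidf.word_idf(term)
        if idf is not None:
            put(f"rel:bw:{term}", tf * idf)

    # word n-grams of surrounding tokens (window around each mention)
    ctx = _context_tokens(doc, left.first, left.last, w) + _context_tokens(
        doc, right.first, right.last, w
    )
    for term, tf in Counter(_word_ngrams(ctx)).items():
        idf = resources.tfidf.word_idf(term)
        if idf is not None:
            put(f"rel:ctx:{term}", tf * idf)

    # entity-level: one-hot types + character n-grams of the mention strings
    put(f"ent:lt={left.etype}", 1.0)
    put(f"ent:rt={right.etype}", 1.0)
    for side, mention in (("lc", left), ("rc", right)):
        for gram, tf in Counter(_char_ngrams(mention.text.lower())).items():
            idf = resources.tfidf.char_idf(gram)
            if idf is not None:
                put(f"ent:{side}:{gram}", tf * idf)

    # semantic types of mention tokens and surrounding context
    mention_words = [
        doc.tokens[i].surface.lower()
        for m in (left, right)
        for i in range(m.first, m.last + 1)
    ]
    for word in mention_words:
        for tag in sorted(resources.tagger.tags(word)):
            put(f"sem:m:{tag}", 1.0)
    for word in ctx:
        for tag in sorted(resources.tagger.tags(word)):
            put(f"sem:c:{tag}", 1.0)

    # word representations: Brown prefixes + WVC ids of context and mention
    # tokens, and the mean embedding of each mention as dense dimensions
    wr_words = mention_words + ctx
    if resources.brown is not None:
        for word in wr_words:
            for prefix in sorted(brown_prefixes(word, resources.brown)):
                put(f"wr:bp:{prefix}", 1.0)
    if resources.wvc is not None:
        for word in wr_words:
            cid = resources.wvc.get(word)
            if cid is not None:
                put(f"wr:wvc:{cid}", 1.0)
    if resources.embeddings is not None:
        for tag, mention in (("l", left), ("r", right)):
            vecs = [
                resources.embeddings.lookup(doc.tokens[i].surface.lower())
                for i in range(mention.first, mention.last + 1)
            ]
            mean = np.mean(vecs, axis=0)
            for i, value in enumerate(mean):
                put(f"wr:emb_{tag}:{i}", float(value))

    return feats
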