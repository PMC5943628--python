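"""Synthetic annotated-corpus generator.

Emulates the statistical shape of an expert-annotated EHR corpus for
medication / adverse-drug-event relation extraction: 9 entity types, 7
relation types with realistic per-type frequencies, a right-skewed token
distance distribution (mode under 9 tokens, long tail crossing sentence
boundaries), and long-distance Indication/Adverse relations.  Entity
surfaces come from type-specific lexicons so the relations are learnable
from lexical plus positional signal.

The generator is deterministic under its seed, and emits documents whose
text is the space-join of their tokens, so standoff round-trips are exact.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import asdict, dataclass, field

import numpy as np

from .resources import BrownPaths, DictionarySemanticTagger, EmbeddingTable
from .standoff import tokenize
from .types import (
    RELATION_SCHEMA,
    RELATION_TYPES,
    AnnotatedDocument,
    EntityMention,
    RelationInstance,
    token_distance,
)


class ConfigError(ValueError):
    """Generator configuration is internally inconsistent or infeasible."""


@dataclass
class Lexicons:
    """Type-specific surface forms plus filler vocabulary."""

    by_type: dict[str, list[str]]
    filler: list[str]

    def words(self) -> list[str]:
        seen: dict[str, None] = {}
        for surfaces in self.by_type.values():
            for s in surfaces:
                for w in s.split(" "):
                    seen.setdefault(w, None)
        for w in self.filler:
            seen.setdefault(w, None)
        seen.setdefault(".", None)
        return list(seen)


def default_lexicons() -> Lexicons:
    return Lexicons(
        by_type={
            "Medication": [
                "albuterol", "rituximab", "romidepsin", "carfilzomib", "ampicillin",
                "penicillin", "prednisone", "metformin", "lisinopril", "warfarin",
                "ibuprofen", "omeprazole", "gabapentin", "furosemide", "atorvastatin",
                "doxorubicin", "cyclophosphamide", "vincristine", "dexamethasone",
                "brentuximab",
            ],
            "Dosage": [
                "10 mg", "2 puffs", "5 ml", "one tablet", "two tablets", "20 mg",
                "40 mg", "half tablet", "100 mg", "2 units", "one capsule", "375 mg",
            ],
            "Route": [
                "orally", "po", "iv", "intravenously", "subcutaneously", "topically",
                "inhaled", "intramuscularly", "sublingual",
            ],
            "Frequency": [
                "daily", "twice daily", "q6h", "q4-6h", "weekly", "at bedtime",
                "every morning", "as needed", "three times daily", "every other day",
            ],
            "Duration": [
                "for 2 weeks", "for 10 days", "for one month", "for 5 days",
                "for 6 cycles", "for 3 months", "for 48 hours",
            ],
            "Indication": [
                "lymphoma", "hypertension", "diabetes", "pneumonia", "lung cancer",
                "myeloma", "anemia", "asthma", "infection", "leukemia", "gout",
                "reflux",
            ],
            "ADE": [
                "rash", "nausea", "neutropenia", "diarrhea", "anaphylaxis",
                "vomiting", "thrombocytopenia", "hepatotoxicity", "mucositis",
                "hyperglycemia", "dizziness", "edema",
            ],
            "Severity": [
                "mild", "moderate", "severe", "grade 2", "grade 3", "worsening",
                "significant", "slight",
            ],
            "OtherSS": [
                "fatigue", "cough", "fever", "headache", "chills", "insomnia",
                "weakness", "malaise",
            ],
        },
        filler=[
            "the", "patient", "was", "seen", "in", "clinic", "today", "and",
            "continues", "on", "therapy", "with", "no", "new", "complaints",
            "will", "follow", "up", "as", "discussed", "course", "remains",
            "stable", "plan", "to", "continue", "current", "regimen", "he",
            "she", "reports", "denies", "noted", "during", "visit", "labs",
            "reviewed", "counts", "recovering", "after", "last", "cycle",
        ],
    )


#: Per-type relation frequencies (training-split counts of the emulated corpus).
DEFAULT_RELATION_RATES: dict[str, float] = {
    "Dosage": 2643.0,
    "Route": 1908.0,
    "Frequency": 2691.0,
    "Duration": 493.0,
    "Indication": 2301.0,
    "Adverse": 717.0,
    "Severity": 1505.0,
}

#: Per-type mean token distances.  Indication (19) and Adverse (14) are the
#: long-distance, often intersentential relations; attribute relations sit
#: next to their drug.  Count-weighted global mean ~= 6.9, emulating 7.
DEFAULT_DISTANCE_MEANS: dict[str, float] = {
    "Dosage": 2.0,
    "Route": 3.0,
    "Frequency": 5.0,
    "Duration": 6.0,
    "Indication": 19.0,
    "Adverse": 14.0,
    "Severity": 2.0,
}

# probability that the Medication (or Severity, for Severity relations)
# mention comes first in document order
_LEFT_FIRST_PROB = {
    "Dosage": 0.8, "Route": 0.8, "Frequency": 0.8, "Duration": 0.8,
    "Indication": 0.5, "Adverse": 0.5, "Severity": 0.8,
}
_ANCHOR_TYPE = {
    "Dosage": "Medication", "Route": "Medication", "Frequency": "Medication",
    "Duration": "Medication", "Indication": "Medication", "Adverse": "Medication",
    "Severity": "Severity",
}


@dataclass
class GenConfig:
    n_docs: int = 100
    relations_per_doc: int = 20
    tokens_per_doc: tuple[int, int] = (250, 450)
    relation_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RELATION_RATES))
    distance_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DISTANCE_MEANS))
    distance_dispersion: float = 2.0
    max_distance: int = 120
    sentence_len_range: tuple[int, int] = (6, 14)
    standalone_mentions_per_doc: int = 20
    gap_mention_prob: float = 0.15
    split_fractions: tuple[float, float, float] = (602 / 791, 95 / 791, 94 / 791)
    lexicons: Lexicons = field(default_factory=default_lexicons)
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 0:
            raise ConfigError("n_docs must be >= 0")
        for t, r in self.relation_rates.items():
            if t not in RELATION_TYPES:
                raise ConfigError(f"unknown relation type in rates: {t!r}")
            if r <= 0:
                raise ConfigError(f"rate for {t} must be positive")
        for t, m in self.distance_means.items():
            if m < 0:
                raise ConfigError(f"distance mean for {t} must be >= 0")
            if m >= self.tokens_per_doc[0]:
                raise ConfigError(
                    f"distance mean {m} for {t} exceeds minimum document length "
                    f"{self.tokens_per_doc[0]}: infeasible"
                )
        if self.distance_dispersion <= 0:
            raise ConfigError("distance_dispersion must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lexicons"] = {"by_type": self.lexicons.by_type, "filler": self.lexicons.filler}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        d = dict(d)
        if "lexicons" in d and isinstance(d["lexicons"], dict):
            d["lexicons"] = Lexicons(**d["lexicons"])
        for key in ("tokens_per_doc", "sentence_len_range", "split_fractions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CorpusSplit:
    train: list[AnnotatedDocument]
    dev: list[AnnotatedDocument]
    test: list[AnnotatedDocument]

    @property
    def all(self) -> list[AnnotatedDocument]:
        return self.train + self.dev + self.test


@dataclass
class CorpusStats:
    n_docs: int
    relation_counts: dict[str, int]
    distance_histogram: dict[int, int]
    mean_distance: float
    max_distance: int
    per_type_mean_distance: dict[str, float]
    mentions_per_doc: float
    relations_per_doc: float

    @property
    def total_relations(self) -> int:
        return sum(self.relation_counts.values())


class _DocBuilder:
    """Accumulates token surfaces + mention spans; sentence breaks in filler only."""

    def __init__(self, cfg: GenConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.surfaces: list[str] = []
        self.mentions: list[tuple[str, str, int, int]] = []  # id, etype, first, last
        self._n_mentions = 0
        self._until_break = int(rng.integers(*cfg.sentence_len_range))

    def _filler_word(self) -> str:
        if self._until_break <= 0:
            self._until_break = int(self.rng.integers(*self.cfg.sentence_len_range))
            return "."
        self._until_break -= 1
        return str(self.rng.choice(self.cfg.lexicons.filler))

    def add_filler(self, n: int) -> None:
        for _ in range(n):
            self.surfaces.append(self._filler_word())

    def add_mention(self, etype: str) -> str:
        surface = str(self.rng.choice(self.cfg.lexicons.by_type[etype]))
        toks = surface.split(" ")
        first = len(self.surfaces)
        self.surfaces.extend(toks)
        self._n_mentions += 1
        mid = f"T{self._n_mentions}"
        self.mentions.append((mid, etype, first, first + len(toks) - 1))
        return mid

    def add_gap(self, d: int) -> None:
        """Exactly ``d`` tokens between a pair: filler, maybe an OtherSS mention."""
        placed = 0
        if d >= 4 and self.rng.random() < self.cfg.gap_mention_prob:
            surface = str(self.rng.choice(self.cfg.lexicons.by_type["OtherSS"]))
            toks = surface.split(" ")
            if len(toks) <= d - 2:
                lead = int(self.rng.integers(1, d - len(toks)))
                self.add_filler(lead)
                first = len(self.surfaces)
                self.surfaces.extend(toks)
                self._n_mentions += 1
                self.mentions.append(
                    (f"T{self._n_mentions}", "OtherSS", first, first + len(toks) - 1)
                )
                placed = lead + len(toks)
        self.add_filler(d - placed)


def _sample_distance(cfg: GenConfig, rtype: str, rng: np.random.Generator) -> int:
    mean = cfg.distance_means[rtype]
    if mean == 0:
        return 0
    n = cfg.distance_dispersion
    if np.isinf(n):  # degenerate: constant distances (controlled experiments)
        return int(round(mean))
    p = n / (n + mean)
    for _ in range(100):
        d = int(rng.negative_binomial(n, p))
        if d <= cfg.max_distance:
            return d
    return cfg.max_distance


def _build_document(cfg: GenConfig, doc_id: str, rng: np.random.Generator) -> AnnotatedDocument:
    b = _DocBuilder(cfg, rng)
    types = list(cfg.relation_rates)
    probs = np.array([cfg.relation_rates[t] for t in types], dtype=float)
    probs /= probs.sum()
    target_len = int(rng.integers(*cfg.tokens_per_doc))

    relations: list[tuple[str, str, str]] = []  # left_id, right_id, label
    n_rel = cfg.relations_per_doc
    n_standalone = cfg.standalone_mentions_per_doc
    standalone_types = [t for t in cfg.lexicons.by_type if cfg.lexicons.by_type[t]]

    events = ["R"] * n_rel + ["S"] * n_standalone
    rng.shuffle(events)
    for ev in events:
        b.add_filler(int(rng.integers(2, 10)))
        if ev == "S":
            b.add_mention(str(rng.choice(standalone_types)))
            continue
        rtype = str(types[rng.choice(len(types), p=probs)])
        anchor = _ANCHOR_TYPE[rtype]
        other = next(iter(RELATION_SCHEMA[rtype] - {anchor}))
        d = _sample_distance(cfg, rtype, rng)
        first_t, second_t = (
            (anchor, other) if rng.random() < _LEFT_FIRST_PROB[rtype] else (other, anchor)
        )
        left = b.add_mention(first_t)
        b.add_gap(d)
        right = b.add_mention(second_t)
        relations.append((left, right, rtype))
    if len(b.surfaces) < target_len:
        b.add_filler(target_len - len(b.surfaces))

    raw_text = " ".join(b.surfaces)
    tokens = tokenize(raw_text)
    assert [t.surface for t in tokens] == b.surfaces, "generator emitted retokenizable text"
    mentions = [
        EntityMention(
            id=mid,
            etype=etype,
            token_span=(first, last),
            text=raw_text[tokens[first].char_start : tokens[last].char_end],
        )
        for mid, etype, first, last in b.mentions
    ]
    rel_objs = [RelationInstance(left_id=a, right_id=c, label=lab) for a, c, lab in relations]
    return AnnotatedDocument(
        doc_id=doc_id, raw_text=raw_text, tokens=tokens, mentions=mentions, relations=rel_objs
    )


def generate_corpus(config: GenConfig) -> CorpusSplit:
    """Generate a deterministic corpus and split it train/dev/test.

    Split proportions default to 602/95/94 over the document count.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(max(config.n_docs, 1))))
    docs = [
        _build_document(config, f"note{idx:0{width}d}", rng) for idx in range(config.n_docs)
    ]
    f_train, f_dev, _ = config.split_fractions
    n = len(docs)
    n_train = int(round(n * f_train))
    n_dev = int(round(n * f_dev))
    return CorpusSplit(
        train=docs[:n_train], dev=docs[n_train : n_train + n_dev], test=docs[n_train + n_dev :]
    )


def corpus_stats(docs: list[AnnotatedDocument]) -> CorpusStats:
    """Descriptive statistics by direct enumeration over the documents."""
    counts: Counter[str] = Counter()
    hist: Counter[int] = Counter()
    dists_by_type: dict[str, list[int]] = {}
    n_mentions = 0
    for doc in docs:
        n_mentions += len(doc.mentions)
        for r in doc.relations:
            d = token_distance(doc, doc.mention(r.left_id), doc.mention(r.right_id))
            counts[r.label] += 1
            hist[d] += 1
            dists_by_type.setdefault(r.label, []).append(d)
    total = sum(counts.values())
    all_d = [d for d, c in hist.items() for _ in range(c)]
    return CorpusStats(
        n_docs=len(docs),
        relation_counts=dict(counts),
        distance_histogram=dict(sorted(hist.items())),
        mean_distance=float(np.mean(all_d)) if all_d else 0.0,
        max_distance=max(hist) if hist else 0,
        per_type_mean_distance={t: float(np.mean(v)) for t, v in dists_by_type.items()},
        mentions_per_doc=n_mentions / len(docs) if docs else 0.0,
        relations_per_doc=total / len(docs) if docs else 0.0,
    )


def synthetic_embeddings(lexicons: Lexicons, dim: int = 50, seed: int = 0) -> EmbeddingTable:
    """Word vectors where same-type lexicon words cluster around a type centroid.

    Emulates distributional embeddings trained on domain text, where words of
    one semantic class occupy a common region of the space.
    """
    rng = np.random.default_rng(seed)
    centroids = {t: rng.normal(size=dim) for t in lexicons.by_type}
    entries: dict[str, np.ndarray] = {}
    for etype, surfaces in lexicons.by_type.items():
        for s in surfaces:
            for w in s.split(" "):
                if w not in entries:
                    entries[w] = centroids[etype] + 0.3 * rng.normal(size=dim)
    for w in lexicons.filler + ["."]:
        if w not in entries:
            entries[w] = rng.normal(size=dim)
    return EmbeddingTable(dimension=dim, entries=entries, unk_vector=np.zeros(dim))


def synthetic_brown_paths(lexicons: Lexicons, seed: int = 0) -> BrownPaths:
    """Bit-string paths whose top levels separate the entity-type lexicons."""
    rng = np.random.default_rng(seed)
    type_prefix = {t: format(i, "04b") for i, t in enumerate(sorted(lexicons.by_type))}
    entries: dict[str, str] = {}
    for etype, surfaces in lexicons.by_type.items():
        for s in surfaces:
            for w in s.split(" "):
                if w not in entries:
                    suffix = "".join(str(int(x)) for x in rng.integers(0, 2, size=8))
                    entries[w] = type_prefix[etype] + suffix
    for w in lexicons.filler:
        if w not in entries:
            suffix = "".join(str(int(x)) for x in rng.integers(0, 2, size=8))
            entries[w] = "1111" + suffix
    return BrownPaths(entries=entries)


def synthetic_semantic_tagger(lexicons: Lexicons) -> DictionarySemanticTagger:
    """Dictionary tagger mapping each lexicon word to its entity-type tag."""
    mapping: dict[str, frozenset[str]] = {}
    for etype, surfaces in lexicons.by_type.items():
        for s in surfaces:
            for w in s.split(" "):
                mapping.setdefault(w, frozenset())
                mapping[w] = mapping[w] | {f"st_{etype.lower()}"}
    return DictionarySemanticTagger(mapping)
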