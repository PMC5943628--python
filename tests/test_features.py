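"""SVM feature families: TF-IDF protocol, Brown prefixes, WVC, extraction."""
import math

import numpy as np
import pytest

from aderex.candidates import CandidateExample, corpus_index, gold_examples
from aderex.features import (
    FeatureResources,
    brown_prefixes,
    compute_wvc,
    extract_features,
    fit_tfidf,
)
from aderex.resources import BrownPaths, EmbeddingTable
from aderex.standoff import read_standoff


class TestTfidf:
    def _three_docs(self):
        texts = ["common alpha here .", "common beta there .", "common gamma where ."]
        return [read_standoff(t, "", f"d{i}") for i, t in enumerate(texts)]

    def test_term_in_every_doc_weight_zero(self):
        stats = fit_tfidf(self._three_docs())
        assert stats.word_idf("common") == pytest.approx(0.0)

    def test_term_in_one_of_three_docs(self):
        stats = fit_tfidf(self._three_docs())
        assert stats.word_idf("alpha") == pytest.approx(math.log(3))

    def test_unseen_term_dropped(self):
        stats = fit_tfidf(self._three_docs())
        assert stats.word_idf("neverseen") is None

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_tfidf([])

    def test_leak_freedom(self, small_split):
        """Dev/test content never alters the fitted statistics."""
        stats_before = fit_tfidf(small_split.train)
        _ = fit_tfidf(small_split.dev)  # fitting elsewhere must not interact
        stats_after = fit_tfidf(small_split.train)
        assert stats_before.word_df == stats_after.word_df
        assert stats_before.char_df == stats_after.char_df
        # applying to a dev doc introduces no new vocabulary
        dev_surfaces = {t.surface.lower() for d in small_split.dev for t in d.tokens}
        new_terms = dev_surfaces - set(stats_before.word_df)
        for term in new_terms:
            assert stats_before.word_idf(term) is None


class TestWvc:
    def test_separable_clusters(self):
        entries = {
            "a1": np.array([0.0, 0.0]), "a2": np.array([0.1, 0.0]),
            "b1": np.array([9.0, 9.0]), "b2": np.array([9.1, 9.0]),
        }
        table = EmbeddingTable(dimension=2, entries=entries)
        wvc = compute_wvc(table, k=2, seed=0)
        assert wvc["a1"] == wvc["a2"] != wvc["b1"] == wvc["b2"]

    def test_k_one_single_cluster(self):
        table = EmbeddingTable(
            dimension=1, entries={"x": np.array([1.0]), "y": np.array([5.0])}
        )
        assert set(compute_wvc(table, k=1, seed=0).values()) == {0}

    def test_objective_beats_random_assignment(self):
        rng = np.random.default_rng(0)
        vectors = rng.normal(size=(500, 8))
        table = EmbeddingTable(
            dimension=8, entries={f"w{i}": vectors[i] for i in range(500)}
        )
        wvc = compute_wvc(table, k=10, seed=0)

        def wcss(assign):
            total = 0.0
            for c in set(assign.values()):
                members = np.stack([vectors[int(w[1:])] for w, a in assign.items() if a == c])
                total += ((members - members.mean(axis=0)) ** 2).sum()
            return total

        random_assign = {f"w{i}": int(rng.integers(0, 10)) for i in range(500)}
        assert wcss(wvc) < wcss(random_assign)


class TestBrownPrefixes:
    paths = BrownPaths(entries={"aspirin": "001011", "rash": "01"})

    def test_prefix_lengths(self):
        assert brown_prefixes("aspirin", self.paths, (4, 6)) == {"0010", "001011"}

    def test_short_bitstring_returned_whole(self):
        assert brown_prefixes("rash", self.paths, (4,)) == {"01"}

    def test_unknown_word_no_features(self):
        assert brown_prefixes("unknown", self.paths) == set()


class TestExtractFeatures:
    @pytest.fixture()
    def setup(self, small_split, small_docs):
        resources = FeatureResources(tfidf=fit_tfidf(small_split.train), window=10)
        examples = gold_examples(small_split.train)
        return resources, examples, small_docs

    def test_numeric_features_copied(self, albuterol_doc, small_split):
        resources = FeatureResources(tfidf=fit_tfidf(small_split.train), window=10)
        ex = CandidateExample("doc", "T1", "T4", "Frequency", "gold")
        feats = extract_features(ex, albuterol_doc, resources)
        # Albuterol ... q4-6h: "2 puffs po" between -> distance 3, 2 mentions
        assert feats["rel:distance"] == 3.0
        assert feats["rel:between"] == 2.0
        assert feats["ent:lt=Medication"] == 1.0
        assert feats["ent:rt=Frequency"] == 1.0

    def test_exactly_one_type_indicator_per_side(self, setup):
        resources, examples, docs = setup
        for ex in examples[:20]:
            feats = extract_features(ex, docs[ex.doc_id], resources)
            assert sum(1 for k in feats if k.startswith("ent:lt=")) == 1
            assert sum(1 for k in feats if k.startswith("ent:rt=")) == 1

    def test_no_stored_zeros_and_determinism(self, setup):
        resources, examples, docs = setup
        ex = examples[0]
        a = extract_features(ex, docs[ex.doc_id], resources)
        b = extract_features(ex, docs[ex.doc_id], resources)
        assert a == b
        assert all(v != 0.0 for v in a.values())

    def test_embedding_family_present_when_resources_given(self, small_split, small_docs):
        from aderex.synthetic import default_lexicons, synthetic_embeddings

        emb = synthetic_embeddings(default_lexicons(), dim=8, seed=0)
        resources = FeatureResources(
            tfidf=fit_tfidf(small_split.train), embeddings=emb, window=10
        )
        ex = gold_examples(small_split.train)[0]
        feats = extract_features(ex, small_docs[ex.doc_id], resources)
        assert any(k.startswith("wr:emb_l:") for k in feats)
        assert any(k.startswith("wr:emb_r:") for k in feats)
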