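"""Shared fixtures: small deterministic synthetic corpora and documents."""
from __future__ import annotations

import pytest

from aderex.candidates import corpus_index
from aderex.standoff import read_standoff
from aderex.synthetic import GenConfig, generate_corpus


def make_doc(text: str, ann: str, doc_id: str = "doc"):
    return read_standoff(text, ann, doc_id)


@pytest.fixture(scope="session")
def small_split():
    """30-document corpus with default statistics; session-cached."""
    return generate_corpus(GenConfig(n_docs=30, seed=7))


@pytest.fixture(scope="session")
def small_docs(small_split):
    return corpus_index(small_split.all)


@pytest.fixture()
def albuterol_doc():
    """Hand-built note with the canonical drug-attributes sentence."""
    text = "She receives Albuterol 2 puffs po q4-6h . He has severe diarrhea ."
    ann = "\n".join(
        [
            "T1\tMedication 13 22\tAlbuterol",
            "T2\tDosage 23 30\t2 puffs",
            "T3\tRoute 31 33\tpo",
            "T4\tFrequency 34 39\tq4-6h",
            "T5\tSeverity 49 55\tsevere",
            "T6\tADE 56 64\tdiarrhea",
            "R1\tDosage Arg1:T1 Arg2:T2",
            "R2\tRoute Arg1:T1 Arg2:T3",
            "R3\tFrequency Arg1:T1 Arg2:T4",
            "R4\tSeverity Arg1:T5 Arg2:T6",
        ]
    )
    return make_doc(text, ann)
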