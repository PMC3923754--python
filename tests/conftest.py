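"""Shared fixtures and small construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from rednotes.corpus import Note, RecordCluster, RecordCorpus, Vocabulary


def corpus_from_token_lists(records: dict[str, dict[str, list[int]]], V: int) -> RecordCorpus:
    """Build a corpus directly from token-id lists (synthetic plumbing)."""
    vocab = Vocabulary(stopword_set=frozenset())
    for i in range(V):
        vocab.add(f"w{i:04d}")
    clusters = []
    for rid in sorted(records):
        notes = []
        for nid in sorted(records[rid]):
            toks = list(records[rid][nid])
            spans = [(2 * i, 2 * i + 1) for i in range(len(toks))]
            notes.append(
                Note(
                    note_id=nid,
                    record_id=rid,
                    raw_text=" ".join(vocab.id_to_term[t] for t in toks),
                    tokens=toks,
                    token_spans=spans,
                )
            )
        clusters.append(RecordCluster(rid, notes))
    corpus = RecordCorpus(clusters, vocab)
    corpus.validate()
    return corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_texts():
    """Two records of three raw-text notes each."""
    return {
        "patientA": {
            "n1": "Pt with chronic kidney disease stage three. Creatinine stable.",
            "n2": "Pt with chronic kidney disease stage three. Creatinine rising today.",
            "n3": "Follow up visit for kidney disease and hypertension management plan.",
        },
        "patientB": {
            "n1": "History of breast cancer, status post mastectomy, doing well.",
            "n2": "Breast cancer surveillance visit, no evidence of recurrence noted.",
            "n3": "Annual exam. Breast cancer history reviewed with the patient today.",
        },
    }
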