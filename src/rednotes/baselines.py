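"""Redundancy-elimination baselines.

Both baselines transform the corpus before running vanilla LDA on the
result: ``delete_doc_transform`` keeps only each record's source note,
``delete_word_transform`` keeps all notes but strips the tokens flagged as
copied.  Vocabularies are shared with the input (no re-pruning) so topic
matrices stay comparable across methods.
"""

from __future__ import annotations

import warnings

from .corpus import Note, RecordCluster, RecordCorpus
from .redundancy import RedundancyAnnotation

__all__ = ["delete_doc_transform", "delete_word_transform"]


def delete_doc_transform(
    corpus: RecordCorpus, annotation: RedundancyAnnotation
) -> RecordCorpus:
    """Keep only the designated source note of every record."""
    clusters = []
    for cluster in corpus.clusters:
        src_id = annotation.source_note[cluster.record_id]
        clusters.append(RecordCluster(cluster.record_id, [cluster.note(src_id)]))
    return RecordCorpus(clusters, corpus.vocabulary)


def delete_word_transform(
    corpus: RecordCorpus, annotation: RedundancyAnnotation
) -> RecordCorpus:
    """Strip copied tokens from non-source notes; drop notes left empty."""
    clusters = []
    for cluster in corpus.clusters:
        src_id = annotation.source_note[cluster.record_id]
        notes = []
        for note in cluster:
            if note.note_id == src_id:
                notes.append(note)
                continue
            flags = annotation.copied[(cluster.record_id, note.note_id)]
            kept = [i for i, f in enumerate(flags) if not f]
            if not kept:
                warnings.warn(
                    f"note {note.note_id!r} of record {cluster.record_id!r} "
                    "is fully copied; dropped"
                )
                continue
            notes.append(
                Note(
                    note_id=note.note_id,
                    record_id=note.record_id,
                    raw_text=note.raw_text,
                    tokens=[note.tokens[i] for i in kept],
                    token_spans=[note.token_spans[i] for i in kept],
                )
            )
        clusters.append(RecordCluster(cluster.record_id, notes))
    return RecordCorpus(clusters, corpus.vocabulary)
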