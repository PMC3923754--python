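"""Data model and I/O for clustered note corpora.

A corpus is a set of *records* (clusters of notes that belong together, e.g.
all notes of one patient); each record holds one or more plain-text notes.
Notes are tokenized against a shared :class:`Vocabulary`, and character
spans of the tokens are retained so that fingerprint matches can be mapped
back onto the original text.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Note",
    "RecordCluster",
    "Vocabulary",
    "RecordCorpus",
    "tokenize",
    "build_corpus",
    "load_corpus",
    "save_corpus",
    "split_by_record",
]

# matched on the original text (case-insensitively) so spans stay valid
# even where unicode lowercasing changes string length
_TOKEN_RE = re.compile(r"[0-9a-z]+", re.IGNORECASE)

#: Minimal default stopword list; callers with domain knowledge should
#: supply their own (clinical corpora typically use a larger list).
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be by for from has he in is it its of on or she
    that the to was were will with this these those not no""".split()
)


def tokenize(text: str, stopwords: Iterable[str] = ()) -> tuple[list[str], list[tuple[int, int]]]:
    """Lowercase word tokenization with character spans.

    Splits on runs of non-alphanumeric characters, lowercases, and drops
    stopwords and single-character tokens.  Spans index into the *original*
    text so later span-level annotation can refer back to it.

    Returns
    -------
    (terms, spans)
        Parallel lists of token strings and ``(char_start, char_end)`` pairs.
    """
    stopset = set(stopwords)
    terms: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0).lower()
        if len(tok) < 2 or tok in stopset:
            continue
        terms.append(tok)
        spans.append((m.start(), m.end()))
    return terms, spans


@dataclass
class Vocabulary:
    """Bijective term <-> integer-id map with an attached stopword set."""

    id_to_term: list[str] = field(default_factory=list)
    term_to_id: dict[str, int] = field(default_factory=dict)
    stopword_set: frozenset[str] = DEFAULT_STOPWORDS

    def __len__(self) -> int:
        return len(self.id_to_term)

    def add(self, term: str) -> int:
        if term in self.term_to_id:
            return self.term_to_id[term]
        idx = len(self.id_to_term)
        self.id_to_term.append(term)
        self.term_to_id[term] = idx
        return idx

    def get(self, term: str) -> int | None:
        return self.term_to_id.get(term)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        min_count: int = 1,
        stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    ) -> "Vocabulary":
        """Build a vocabulary from term counts, dropping rare terms.

        Terms are assigned ids in sorted order so the mapping is
        deterministic regardless of counting order.
        """
        vocab = cls(stopword_set=frozenset(stopwords))
        for term in sorted(t for t, c in counts.items() if c >= min_count):
            vocab.add(term)
        return vocab


@dataclass
class Note:
    """A single tokenized note."""

    note_id: str
    record_id: str
    raw_text: str
    tokens: list[int]
    token_spans: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.tokens)

    def validate(self, vocab_size: int) -> None:
        if len(self.tokens) != len(self.token_spans):
            raise ValueError(f"note {self.note_id}: tokens/spans length mismatch")
        if self.tokens and max(self.tokens) >= vocab_size:
            raise ValueError(f"note {self.note_id}: token id out of vocabulary range")
        prev_end = -1
        for start, end in self.token_spans:
            if start < prev_end or end <= start:
                raise ValueError(f"note {self.note_id}: token spans overlap or are unordered")
            prev_end = end


@dataclass
class RecordCluster:
    """All notes belonging to one record (one patient)."""

    record_id: str
    notes: list[Note]

    def __len__(self) -> int:
        return len(self.notes)

    def __iter__(self) -> Iterator[Note]:
        return iter(self.notes)

    def note(self, note_id: str) -> Note:
        for n in self.notes:
            if n.note_id == note_id:
                return n
        raise KeyError(f"no note {note_id!r} in record {self.record_id!r}")


@dataclass
class RecordCorpus:
    """A collection of record clusters sharing one vocabulary."""

    clusters: list[RecordCluster]
    vocabulary: Vocabulary

    @property
    def n_records(self) -> int:
        return len(self.clusters)

    @property
    def n_notes(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def n_tokens(self) -> int:
        return sum(len(n) for c in self.clusters for n in c)

    def iter_notes(self) -> Iterator[Note]:
        for cluster in self.clusters:
            yield from cluster.notes

    def validate(self) -> None:
        v = len(self.vocabulary)
        for cluster in self.clusters:
            if not cluster.notes:
                raise ValueError(f"record {cluster.record_id!r} has no notes")
            seen = set()
            for note in cluster:
                if note.note_id in seen:
                    raise ValueError(
                        f"duplicate note_id {note.note_id!r} in record {cluster.record_id!r}"
                    )
                seen.add(note.note_id)
                note.validate(v)


def build_corpus(
    records: dict[str, dict[str, str]],
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    min_count: int = 1,
) -> RecordCorpus:
    """Tokenize raw texts into a :class:`RecordCorpus`.

    Parameters
    ----------
    records
        ``{record_id: {note_id: raw_text}}``.
    stopwords
        Terms to drop during tokenization.
    min_count
        Terms occurring fewer than this many times across the whole input
        are dropped from the vocabulary (and from the notes).
    """
    tokenized: dict[str, dict[str, tuple[str, list[str], list[tuple[int, int]]]]] = {}
    counts: dict[str, int] = {}
    for rid in sorted(records):
        tokenized[rid] = {}
        for nid in sorted(records[rid]):
            text = records[rid][nid]
            terms, spans = tokenize(text, stopwords)
            tokenized[rid][nid] = (text, terms, spans)
            for t in terms:
                counts[t] = counts.get(t, 0) + 1

    vocab = Vocabulary.from_counts(counts, min_count=min_count, stopwords=stopwords)
    clusters = []
    for rid in sorted(tokenized):
        notes = []
        for nid in sorted(tokenized[rid]):
            text, terms, spans = tokenized[rid][nid]
            ids, kept_spans = [], []
            for term, span in zip(terms, spans):
                tid = vocab.get(term)
                if tid is not None:
                    ids.append(tid)
                    kept_spans.append(span)
            notes.append(Note(nid, rid, text, ids, kept_spans))
        clusters.append(RecordCluster(rid, notes))
    corpus = RecordCorpus(clusters, vocab)
    corpus.validate()
    return corpus


def _read_dir(path: Path) -> dict[str, dict[str, str]]:
    records: dict[str, dict[str, str]] = {}
    for record_dir in sorted(p for p in path.iterdir() if p.is_dir()):
        notes = {
            f.stem: f.read_text(encoding="utf-8")
            for f in sorted(record_dir.glob("*.txt"))
        }
        if not notes:
            warnings.warn(f"record directory {record_dir} is empty; skipped")
            continue
        records[record_dir.name] = notes
    return records


def _read_jsonl(path: Path) -> dict[str, dict[str, str]]:
    records: dict[str, dict[str, str]] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            rid, nid = str(obj["record_id"]), str(obj["note_id"])
            bucket = records.setdefault(rid, {})
            if nid in bucket:
                raise ValueError(f"duplicate note_id {nid!r} in record {rid!r}")
            bucket[nid] = obj["text"]
    return records


def load_corpus(
    path: str | Path,
    format: str = "dir",
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    min_count: int = 1,
) -> RecordCorpus:
    """Load a corpus from disk.

    ``dir`` format expects ``<root>/<record_id>/<note_id>.txt``;
    ``jsonl`` expects one object per line with keys ``record_id``,
    ``note_id`` and ``text``.  Ordering is deterministic: records sorted by
    record_id, notes by note_id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus path does not exist: {path}")
    if format == "dir":
        records = _read_dir(path)
    elif format == "jsonl":
        records = _read_jsonl(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    if not records:
        raise ValueError("empty corpus")
    return build_corpus(records, stopwords=stopwords, min_count=min_count)


def save_corpus(corpus: RecordCorpus, path: str | Path) -> None:
    """Write the corpus as jsonl, one note per line, with resolved tokens."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for note in corpus.iter_notes():
            obj = {
                "record_id": note.record_id,
                "note_id": note.note_id,
                "text": note.raw_text,
                "tokens": [corpus.vocabulary.id_to_term[t] for t in note.tokens],
            }
            fh.write(json.dumps(obj) + "\n")


def split_by_record(
    corpus: RecordCorpus,
    n_test_records: int,
    seed: int,
    annotation,
    max_test_redundancy: float = 0.15,
) -> tuple[RecordCorpus, list[Note]]:
    """Held-out split at the record level.

    Test records are drawn uniformly at random (seeded) and are disjoint
    from the training records.  From each test record exactly one *low
    redundancy* note is taken: the note with the smallest copied-token
    fraction, provided that fraction is at most ``max_test_redundancy``
    (ties broken by earliest note_id).  Records with no qualifying note are
    redrawn from the remaining pool.

    Returns ``(train_corpus, test_notes)``.  The train corpus shares the
    vocabulary object with the input.
    """
    from .redundancy import redundancy_fraction

    if n_test_records > corpus.n_records:
        raise ValueError(
            f"cannot hold out {n_test_records} of {corpus.n_records} records"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(corpus.n_records)

    test_ids: set[str] = set()
    test_notes: list[Note] = []
    for idx in order:
        if len(test_notes) == n_test_records:
            break
        cluster = corpus.clusters[idx]
        best: Note | None = None
        best_frac = None
        for note in sorted(cluster.notes, key=lambda n: n.note_id):
            frac = redundancy_fraction(annotation, cluster.record_id, note.note_id)
            if frac <= max_test_redundancy and (best_frac is None or frac < best_frac):
                best, best_frac = note, frac
        if best is not None:
            test_ids.add(cluster.record_id)
            test_notes.append(best)
    if len(test_notes) < n_test_records:
        raise ValueError(
            f"only {len(test_notes)} records have a note with redundancy "
            f"<= {max_test_redundancy}; requested {n_test_records}"
        )
    train = RecordCorpus(
        [c for c in corpus.clusters if c.record_id not in test_ids],
        corpus.vocabulary,
    )
    return train, test_notes
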