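"""Copy-paste redundancy detection within record clusters.

Each record designates one *source note* (the longest).  Every other note is
compared against the source with k-gram fingerprinting: token k-grams are
hashed, a winnowing pass keeps one fingerprint per sliding window, and
fingerprint hits are extended to maximal exact token runs.  Runs of at
least ``min_span`` tokens are flagged as copied, token by token, with an
alignment back to the source position.

The winnowing window is clamped to ``min_span - k + 1`` so that every
shared run of at least ``min_span`` tokens is guaranteed to contain a
selected fingerprint and hence be detected (a run of length L contains
``L - k + 1`` k-grams, and winnowing selects at least one fingerprint out of
any ``window`` consecutive k-grams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .corpus import Note, RecordCluster, RecordCorpus

__all__ = [
    "RedundancyAnnotation",
    "SimilarityReport",
    "select_source",
    "annotate_redundancy",
    "annotate_corpus",
    "redundancy_fraction",
    "smith_waterman_similarity",
    "corpus_similarity_report",
]

NONE_POS = -1  # sentinel for "not copied" in source_pos dumps


@dataclass
class RedundancyAnnotation:
    """Per-token copied flags plus per-record source note designation.

    ``copied[(record_id, note_id)]`` is a boolean list aligned to the note's
    tokens; ``source_pos`` holds, for every copied token, the token index in
    the record's source note it was copied from (``None`` otherwise).
    """

    source_note: dict[str, str] = field(default_factory=dict)
    copied: dict[tuple[str, str], list[bool]] = field(default_factory=dict)
    source_pos: dict[tuple[str, str], list[int | None]] = field(default_factory=dict)

    def n_copied(self) -> int:
        return sum(sum(flags) for flags in self.copied.values())

    def covers(self, corpus: RecordCorpus) -> bool:
        return all(
            (n.record_id, n.note_id) in self.copied for n in corpus.iter_notes()
        )

    def merge(self, other: "RedundancyAnnotation") -> None:
        self.source_note.update(other.source_note)
        self.copied.update(other.copied)
        self.source_pos.update(other.source_pos)

    @classmethod
    def empty(cls, corpus: RecordCorpus) -> "RedundancyAnnotation":
        """Annotation with no copied tokens (sources still designated)."""
        ann = cls()
        for cluster in corpus.clusters:
            ann.source_note[cluster.record_id] = select_source(cluster)
            for note in cluster:
                key = (cluster.record_id, note.note_id)
                ann.copied[key] = [False] * len(note)
                ann.source_pos[key] = [None] * len(note)
        return ann

    def validate(self, corpus: RecordCorpus) -> None:
        for cluster in corpus.clusters:
            src_id = self.source_note[cluster.record_id]
            src = cluster.note(src_id)
            for note in cluster:
                key = (cluster.record_id, note.note_id)
                flags, pos = self.copied[key], self.source_pos[key]
                if len(flags) != len(note) or len(pos) != len(note):
                    raise ValueError(f"annotation length mismatch for {key}")
                for i, (f, p) in enumerate(zip(flags, pos)):
                    if f != (p is not None):
                        raise ValueError(f"flag/source_pos inconsistency at {key}[{i}]")
                    if note.note_id == src_id and f:
                        raise ValueError(f"source note has copied token at {key}[{i}]")
                    if p is not None and note.tokens[i] != src.tokens[p]:
                        raise ValueError(f"copied token mismatch at {key}[{i}]")


def save_annotation(annotation: RedundancyAnnotation, path) -> None:
    """Dump an annotation as jsonl (one note per line, -1 = not copied)."""
    import json
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        for (rid, nid), flags in annotation.copied.items():
            obj = {
                "record_id": rid,
                "note_id": nid,
                "source_note": annotation.source_note[rid],
                "copied": [int(f) for f in flags],
                "source_pos": [
                    NONE_POS if p is None else p
                    for p in annotation.source_pos[(rid, nid)]
                ],
            }
            fh.write(json.dumps(obj) + "\n")


def load_annotation(path) -> RedundancyAnnotation:
    """Read an annotation dumped by :func:`save_annotation`."""
    import json
    from pathlib import Path

    ann = RedundancyAnnotation()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            key = (obj["record_id"], obj["note_id"])
            ann.source_note[obj["record_id"]] = obj["source_note"]
            ann.copied[key] = [bool(f) for f in obj["copied"]]
            ann.source_pos[key] = [
                None if p == NONE_POS else p for p in obj["source_pos"]
            ]
    return ann


def select_source(cluster: RecordCluster) -> str:
    """Source note id: the longest note, ties broken by earliest note_id."""
    if not cluster.notes:
        raise ValueError(f"record {cluster.record_id!r} has no notes")
    return min(cluster.notes, key=lambda n: (-len(n), n.note_id)).note_id


def _kgram_hashes(tokens: list[int], k: int) -> np.ndarray:
    """Deterministic polynomial hashes of all token k-grams."""
    n = len(tokens) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    arr = np.asarray(tokens, dtype=np.uint64)
    base = np.uint64(1000003)
    h = np.zeros(n, dtype=np.uint64)
    # h[i] = sum_j tokens[i+j] * base**(k-1-j)  (mod 2**64)
    with np.errstate(over="ignore"):
        for j in range(k):
            h = h * base + arr[j : j + n]
    return h


def _winnow(hashes: np.ndarray, window: int) -> list[int]:
    """Indices of winnowing-selected fingerprints (rightmost min per window)."""
    n = len(hashes)
    if n == 0:
        return []
    if window <= 1 or n <= window:
        return list(range(n))
    selected: set[int] = set()
    for start in range(n - window + 1):
        w = hashes[start : start + window]
        # rightmost minimum for robust winnowing
        idx = start + window - 1 - int(np.argmin(w[::-1]))
        selected.add(idx)
    return sorted(selected)


def _extend(copy_toks: list[int], src_toks: list[int], ci: int, si: int) -> tuple[int, int, int]:
    """Maximal exact run through the matching seed (ci, si)."""
    a, b = ci, si
    while a > 0 and b > 0 and copy_toks[a - 1] == src_toks[b - 1]:
        a -= 1
        b -= 1
    length = 0
    while (
        ci + length < len(copy_toks)
        and si + length < len(src_toks)
        and copy_toks[ci + length] == src_toks[si + length]
    ):
        length += 1
    # re-anchor at run start
    return a, b, (ci - a) + length


def _shared_spans(
    copy_toks: list[int], src_toks: list[int], k: int, window: int, min_span: int
) -> list[tuple[int, int, int]]:
    """Maximal shared runs >= min_span, greedily resolved on the copy side.

    Returns accepted ``(copy_start, src_start, length)`` spans; greedy order
    is longest first, then leftmost in the copy, then leftmost in the source;
    spans overlapping an already accepted copy region are skipped.
    """
    if len(copy_toks) < k or len(src_toks) < k:
        return []
    eff_window = max(1, min(window, min_span - k + 1))
    src_hashes = _kgram_hashes(src_toks, k)
    src_index: dict[int, list[int]] = {}
    for i, h in enumerate(src_hashes):
        src_index.setdefault(int(h), []).append(i)

    copy_hashes = _kgram_hashes(copy_toks, k)
    candidates: set[tuple[int, int, int]] = set()
    for ci in _winnow(copy_hashes, eff_window):
        for si in src_index.get(int(copy_hashes[ci]), ()):
            if copy_toks[ci : ci + k] != src_toks[si : si + k]:
                continue  # hash collision
            span = _extend(copy_toks, src_toks, ci, si)
            if span[2] >= min_span:
                candidates.add(span)

    accepted: list[tuple[int, int, int]] = []
    taken = [False] * len(copy_toks)
    for cs, ss, length in sorted(candidates, key=lambda s: (-s[2], s[0], s[1])):
        if any(taken[cs : cs + length]):
            continue
        accepted.append((cs, ss, length))
        for i in range(cs, cs + length):
            taken[i] = True
    return accepted


def annotate_redundancy(
    cluster: RecordCluster, k: int = 8, window: int = 4, min_span: int = 10
) -> RedundancyAnnotation:
    """Detect copied spans in one record cluster.

    Every non-source note is fingerprint-aligned against the record's
    source note; tokens inside shared runs of at least ``min_span`` tokens
    are flagged copied with their aligned source position.
    """
    if k < 2:
        raise ValueError("k-gram length must be >= 2")
    if min_span < k:
        raise ValueError("min_span must be >= k")
    ann = RedundancyAnnotation()
    src_id = select_source(cluster)
    ann.source_note[cluster.record_id] = src_id
    src = cluster.note(src_id)
    for note in cluster:
        key = (cluster.record_id, note.note_id)
        flags: list[bool] = [False] * len(note)
        pos: list[int | None] = [None] * len(note)
        if note.note_id != src_id:
            for cs, ss, length in _shared_spans(note.tokens, src.tokens, k, window, min_span):
                for off in range(length):
                    flags[cs + off] = True
                    pos[cs + off] = ss + off
        ann.copied[key] = flags
        ann.source_pos[key] = pos
    return ann


def annotate_corpus(
    corpus: RecordCorpus, k: int = 8, window: int = 4, min_span: int = 10
) -> RedundancyAnnotation:
    """Run :func:`annotate_redundancy` over every record of a corpus."""
    ann = RedundancyAnnotation()
    for cluster in corpus.clusters:
        ann.merge(annotate_redundancy(cluster, k=k, window=window, min_span=min_span))
    return ann


def redundancy_fraction(
    annotation: RedundancyAnnotation, record_id: str, note_id: str
) -> float:
    """Fraction of a note's tokens flagged as copied (0 for empty notes)."""
    flags = annotation.copied[(record_id, note_id)]
    if not flags:
        return 0.0
    return sum(flags) / len(flags)


# Local alignment of token sequences goes through Biopython's pairwise
# aligner; token ids are mapped to private unicode codepoints so arbitrary
# vocabularies fit the string interface.
_CHR_OFFSET = 0x100
_SURROGATE_LO, _SURROGATE_HI = 0xD800, 0xE000


def _tokens_to_text(tokens: list[int]) -> str:
    out = []
    for t in tokens:
        cp = t + _CHR_OFFSET
        if cp >= _SURROGATE_LO:
            cp += _SURROGATE_HI - _SURROGATE_LO
        out.append(chr(cp))
    return "".join(out)


def smith_waterman_similarity(
    note_a: Note | list[int],
    note_b: Note | list[int],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> float:
    """Token-level local-alignment similarity in [0, 1].

    The Smith-Waterman score of the two token sequences, normalized by
    ``match * min(len_a, len_b)`` (the score of aligning the shorter
    sequence perfectly) and clamped to [0, 1].  Empty input scores 0.
    """
    toks_a = note_a.tokens if isinstance(note_a, Note) else list(note_a)
    toks_b = note_b.tokens if isinstance(note_b, Note) else list(note_b)
    if not toks_a or not toks_b:
        return 0.0
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )
    score = aligner.score(_tokens_to_text(toks_a), _tokens_to_text(toks_b))
    denom = match * min(len(toks_a), len(toks_b))
    return float(min(1.0, max(0.0, score / denom)))


@dataclass
class SimilarityReport:
    """Sampled same-record pairwise similarities."""

    pairs: list[tuple[str, str, float]]
    mean_same_record_similarity: float


def corpus_similarity_report(
    corpus: RecordCorpus,
    n_pairs: int,
    seed: int,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> SimilarityReport:
    """Characterize corpus redundancy by sampling same-record note pairs.

    Draws ``n_pairs`` unordered note pairs uniformly from records with at
    least two notes and reports Smith-Waterman similarities and their mean.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    eligible = [c for c in corpus.clusters if len(c) >= 2]
    if not eligible:
        raise ValueError("no record has >= 2 notes")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        cluster = eligible[rng.integers(len(eligible))]
        i, j = rng.choice(len(cluster.notes), size=2, replace=False)
        a, b = cluster.notes[int(i)], cluster.notes[int(j)]
        sim = smith_waterman_similarity(a, b, match=match, mismatch=mismatch, gap=gap)
        pairs.append((a.note_id, b.note_id, sim))
    mean = float(np.mean([p[2] for p in pairs]))
    return SimilarityReport(pairs=pairs, mean_same_record_similarity=mean)
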