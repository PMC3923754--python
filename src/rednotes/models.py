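"""Topic models: vanilla LDA and its redundancy-aware variant.

Both models are collapsed Gibbs samplers sharing one sweep kernel and are
exposed as scikit-learn style estimators (``fit``, fitted attributes with a
trailing underscore, ``get_params``/``set_params``).

The redundancy-aware model treats each record's designated *source note* as
generated by the ordinary LDA process, while tokens of other notes that
were flagged as copied from the source are handled specially:

- a copied token draws its topic from the source note's **current**
  assignments of the same word, smoothed by ``delta``
  (p(k) proportional to n_src(w, k) + delta);
- if the flagged word does not occur in the source note (detector/source
  mismatch), the token falls back to the standard conditional computed on
  redundancy-excluded counts;
- copied tokens never enter the topic-word counts used to estimate the
  topic-word distribution phi — this is the exclusion rule that stops
  pasted text from inflating a word's weight in its topic — but they do
  count toward their own note's topic mixture theta.

With an annotation containing no copied tokens the redundancy-aware
sampler reduces *bit-exactly* to vanilla LDA under the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from ._gibbs import fold_in_sweeps, gibbs_sweeps, gibbs_sweeps_py
from .corpus import Note, RecordCorpus, Vocabulary
from .redundancy import RedundancyAnnotation, select_source

__all__ = [
    "HyperParams",
    "SamplerState",
    "TopicModel",
    "VanillaLDA",
    "RedLDA",
    "fit_vanilla_lda",
    "fit_red_lda",
    "infer_theta",
    "gibbs_conditional_vanilla",
    "gibbs_conditional_copied",
    "gibbs_conditional_copied_fallback",
]

#: sweeps of random draws generated per kernel call (bounds peak memory)
_SWEEP_CHUNK = 200


@dataclass
class HyperParams:
    """Sampler hyperparameters.

    ``alpha`` is the symmetric Dirichlet prior on document-topic mixtures
    (``None`` resolves to the common 50/K heuristic), ``beta`` the prior on
    topic-word distributions, and ``delta`` the smoothing added to source
    occurrence counts when a copied token samples its topic.
    """

    K: int = 50
    alpha: float | None = None
    beta: float = 0.01
    delta: float = 0.1
    n_iterations: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha is None:
            self.alpha = 50.0 / self.K
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie strictly between 0 and 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


@dataclass
class _Layout:
    """Flattened token arrays in sweep visit order."""

    word: np.ndarray  # (T,) int32 token ids
    doc_of: np.ndarray  # (T,) int32 document index
    is_copied: np.ndarray  # (T,) bool
    counted: np.ndarray  # (T,) bool
    src_ptr: np.ndarray  # (T+1,) int64 CSR pointers
    src_idx: np.ndarray  # int32 flat positions of same-word source tokens
    doc_ids: list  # [(record_id, note_id)] in document-index order
    doc_start: np.ndarray  # (D+1,) flat offset of each document
    source_range: dict  # record_id -> (flat_start, flat_end) of source note


def _build_layout(
    corpus: RecordCorpus,
    annotation: RedundancyAnnotation | None,
    exclude_copied: bool,
) -> _Layout:
    """Flatten a corpus for the sweep kernel.

    Visit order is canonical for both models: clusters in corpus order and
    the record's source note first (the annotation's designation when
    given, otherwise the longest note), so that copied tokens always sample
    against fresh source assignments and the two samplers share draw
    sequences on redundancy-free input.
    """
    word_l, doc_l, copied_l = [], [], []
    doc_ids: list[tuple[str, str]] = []
    doc_start = [0]
    source_range: dict[str, tuple[int, int]] = {}
    note_flat: dict[tuple[str, str], int] = {}

    for cluster in corpus.clusters:
        if annotation is not None:
            src_id = annotation.source_note[cluster.record_id]
        else:
            src_id = select_source(cluster)
        ordered = [cluster.note(src_id)] + [
            n for n in cluster.notes if n.note_id != src_id
        ]
        for note in ordered:
            key = (cluster.record_id, note.note_id)
            d = len(doc_ids)
            start = len(word_l)
            note_flat[key] = start
            doc_ids.append(key)
            if annotation is not None:
                if key not in annotation.copied:
                    raise ValueError(f"annotation missing note {key}")
                flags = annotation.copied[key]
            else:
                flags = [False] * len(note)
            word_l.extend(note.tokens)
            doc_l.extend([d] * len(note))
            copied_l.extend(flags)
            if note.note_id == src_id:
                source_range[cluster.record_id] = (start, start + len(note))
            doc_start.append(len(word_l))

    T = len(word_l)
    word = np.asarray(word_l, dtype=np.int32)
    doc_of = np.asarray(doc_l, dtype=np.int32)
    is_copied = np.asarray(copied_l, dtype=bool)
    counted = ~is_copied if exclude_copied else np.ones(T, dtype=bool)

    # CSR of same-word source-note positions, for copied tokens only
    src_ptr = np.zeros(T + 1, dtype=np.int64)
    src_idx_l: list[int] = []
    # per record: word -> flat positions in source note
    src_occ: dict[str, dict[int, list[int]]] = {}
    for rid, (lo, hi) in source_range.items():
        occ: dict[int, list[int]] = {}
        for t in range(lo, hi):
            occ.setdefault(int(word[t]), []).append(t)
        src_occ[rid] = occ
    for t in range(T):
        if is_copied[t]:
            rid = doc_ids[doc_of[t]][0]
            src_idx_l.extend(src_occ[rid].get(int(word[t]), ()))
        src_ptr[t + 1] = len(src_idx_l)
    src_idx = np.asarray(src_idx_l, dtype=np.int32)

    return _Layout(
        word=word,
        doc_of=doc_of,
        is_copied=is_copied,
        counted=counted,
        src_ptr=src_ptr,
        src_idx=src_idx,
        doc_ids=doc_ids,
        doc_start=np.asarray(doc_start, dtype=np.int64),
        source_range=source_range,
    )


@dataclass
class SamplerState:
    """Topic assignments plus the count matrices the conditionals read."""

    z: np.ndarray  # (T,) int32
    n_dk: np.ndarray  # (D, K) int64
    n_kw: np.ndarray  # (K, V) int64
    n_k: np.ndarray  # (K,) int64
    layout: _Layout
    K: int
    V: int

    def recompute_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """From-scratch count matrices implied by ``z`` and the flags."""
        D = len(self.layout.doc_ids)
        n_dk = np.zeros((D, self.K), dtype=np.int64)
        n_kw = np.zeros((self.K, self.V), dtype=np.int64)
        n_k = np.zeros(self.K, dtype=np.int64)
        for t in range(len(self.z)):
            k = int(self.z[t])
            n_dk[self.layout.doc_of[t], k] += 1
            if self.layout.counted[t]:
                n_kw[k, self.layout.word[t]] += 1
                n_k[k] += 1
        return n_dk, n_kw, n_k

    def source_word_topic_counts(self, record_id: str, w: int) -> np.ndarray:
        """n_src(w, k): occurrences of word w per topic in the source note."""
        lo, hi = self.layout.source_range[record_id]
        counts = np.zeros(self.K, dtype=np.int64)
        for t in range(lo, hi):
            if int(self.layout.word[t]) == w:
                counts[int(self.z[t])] += 1
        return counts


def gibbs_conditional_vanilla(
    state: SamplerState, d: int, w: int, alpha: float, beta: float
) -> np.ndarray:
    """Standard collapsed-Gibbs conditional over topics for token word w.

    Assumes the token under resampling is already decremented from the
    counts.  p(k) proportional to (n_dk + alpha)(n_kw + beta)/(n_k + V beta).
    """
    p = (
        (state.n_dk[d] + alpha)
        * (state.n_kw[:, w] + beta)
        / (state.n_k + state.V * beta)
    )
    return p / p.sum()


def gibbs_conditional_copied(
    state: SamplerState, record_id: str, w: int, delta: float
) -> np.ndarray:
    """Conditional for a copied token whose word occurs in the source note.

    p(k) proportional to n_src(w, k) + delta over the source note's current
    assignments.
    """
    counts = state.source_word_topic_counts(record_id, w)
    if counts.sum() == 0:
        raise ValueError(
            f"word {w} absent from source note of record {record_id!r}; "
            "use the fallback conditional"
        )
    p = counts + delta
    return p / p.sum()


def gibbs_conditional_copied_fallback(
    state: SamplerState, d: int, w: int, alpha: float, beta: float
) -> np.ndarray:
    """Conditional for a copied token whose word is absent from the source.

    Functionally the standard conditional, but over counts from which all
    copied tokens are excluded — which is exactly what the state's
    ``n_kw``/``n_k`` hold under the redundancy-aware model.
    """
    return gibbs_conditional_vanilla(state, d, w, alpha, beta)


@dataclass
class TopicModel:
    """Point estimates of the topic-word (phi) and doc-topic (theta) laws."""

    phi: np.ndarray  # (K, V)
    theta: np.ndarray  # (D, K)
    doc_ids: list
    alpha: float
    beta: float
    vocabulary: Vocabulary | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    @property
    def vocab_size(self) -> int:
        return self.phi.shape[1]

    def top_words(self, topic: int, top_m: int = 20) -> list[tuple[str, float]]:
        order = np.argsort(self.phi[topic])[::-1][:top_m]
        terms = self.vocabulary.id_to_term if self.vocabulary else None
        return [
            (terms[i] if terms else str(i), float(self.phi[topic, i])) for i in order
        ]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "phi.tsv", self.phi, delimiter="\t")
        np.savetxt(path / "theta.tsv", self.theta, delimiter="\t")
        if self.vocabulary is not None:
            (path / "vocab.txt").write_text(
                "\n".join(self.vocabulary.id_to_term) + "\n", encoding="utf-8"
            )
        meta = dict(self.meta)
        meta.update(
            {
                "alpha": self.alpha,
                "beta": self.beta,
                "doc_ids": [list(d) for d in self.doc_ids],
            }
        )
        (path / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TopicModel":
        path = Path(path)
        phi = np.atleast_2d(np.loadtxt(path / "phi.tsv", delimiter="\t"))
        theta = np.atleast_2d(np.loadtxt(path / "theta.tsv", delimiter="\t"))
        meta = json.loads((path / "meta.json").read_text(encoding="utf-8"))
        vocab = None
        vfile = path / "vocab.txt"
        if vfile.exists():
            terms = vfile.read_text(encoding="utf-8").splitlines()
            vocab = Vocabulary(
                id_to_term=terms, term_to_id={t: i for i, t in enumerate(terms)}
            )
        doc_ids = [tuple(d) for d in meta.pop("doc_ids", [])]
        return cls(
            phi=phi,
            theta=theta,
            doc_ids=doc_ids,
            alpha=meta.pop("alpha"),
            beta=meta.pop("beta"),
            vocabulary=vocab,
            meta=meta,
        )


class VanillaLDA(BaseEstimator):
    """Latent Dirichlet Allocation fit by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : int
        Number of topics K.
    alpha : float or None
        Symmetric document-topic Dirichlet prior; ``None`` means 50/K.
    beta : float
        Symmetric topic-word Dirichlet prior.
    n_iterations : int
        Full Gibbs sweeps over the corpus.
    random_state : int
        Seed for initialization and all sweep draws; fits are bit-for-bit
        reproducible given the same seed and corpus.

    Attributes
    ----------
    components_ : (K, V) ndarray
        Topic-word probabilities phi (rows sum to 1).
    theta_ : (D, K) ndarray
        Document-topic probabilities, rows aligned with ``doc_ids_``.
    doc_ids_ : list of (record_id, note_id)
    state_ : SamplerState
        Final topic assignments and count matrices.
    """

    _exclude_copied = False

    def __init__(
        self,
        n_topics: int = 50,
        alpha: float | None = None,
        beta: float = 0.01,
        delta: float = 0.1,
        n_iterations: int = 2000,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.delta = delta
        self.n_iterations = n_iterations
        self.random_state = random_state

    def _hyper(self) -> HyperParams:
        return HyperParams(
            K=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            delta=self.delta,
            n_iterations=self.n_iterations,
            seed=self.random_state,
        )

    def fit(
        self,
        X: RecordCorpus,
        y=None,
        annotation: RedundancyAnnotation | None = None,
        use_python_kernel: bool = False,
    ):
        """Run the sampler on corpus ``X``.

        ``annotation`` is ignored by vanilla LDA except for sweep ordering
        (source note first), which keeps the draw sequence comparable with
        the redundancy-aware sampler.  ``use_python_kernel`` switches to
        the pure-Python sweep mirror (slow; testing only).
        """
        if X.n_tokens == 0:
            raise ValueError("cannot fit on an empty corpus")
        hyper = self._hyper()
        layout = _build_layout(X, annotation, exclude_copied=self._exclude_copied)
        K, V = hyper.K, len(X.vocabulary)
        T = len(layout.word)
        rng = np.random.default_rng(hyper.seed)
        z = rng.integers(0, K, size=T, dtype=np.int32)

        D = len(layout.doc_ids)
        n_dk = np.zeros((D, K), dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        n_k = np.zeros(K, dtype=np.int64)
        np.add.at(n_dk, (layout.doc_of, z), 1)
        cmask = layout.counted
        np.add.at(n_kw, (z[cmask], layout.word[cmask]), 1)
        np.add.at(n_k, z[cmask], 1)

        kernel = gibbs_sweeps_py if use_python_kernel else gibbs_sweeps
        done = 0
        while done < hyper.n_iterations:
            chunk = min(_SWEEP_CHUNK, hyper.n_iterations - done)
            uniforms = rng.random((chunk, T))
            kernel(
                z,
                layout.word,
                layout.doc_of,
                layout.counted,
                layout.is_copied,
                layout.src_ptr,
                layout.src_idx,
                n_dk,
                n_kw,
                n_k,
                hyper.alpha,
                hyper.beta,
                hyper.delta,
                uniforms,
            )
            done += chunk

        self.state_ = SamplerState(
            z=z, n_dk=n_dk, n_kw=n_kw, n_k=n_k, layout=layout, K=K, V=V
        )
        self.components_ = (n_kw + hyper.beta) / (
            n_k[:, None] + V * hyper.beta
        )
        doc_len = np.diff(layout.doc_start)
        self.theta_ = (n_dk + hyper.alpha) / (
            doc_len[:, None] + K * hyper.alpha
        )
        self.doc_ids_ = list(layout.doc_ids)
        self.vocabulary_ = X.vocabulary
        self.alpha_ = hyper.alpha
        return self

    def to_topic_model(self) -> TopicModel:
        return TopicModel(
            phi=self.components_,
            theta=self.theta_,
            doc_ids=self.doc_ids_,
            alpha=self.alpha_,
            beta=self.beta,
            vocabulary=self.vocabulary_,
            meta={
                "method": type(self).__name__,
                "n_iterations": self.n_iterations,
                "seed": self.random_state,
            },
        )


class RedLDA(VanillaLDA):
    """Redundancy-aware LDA.

    Requires a :class:`RedundancyAnnotation` at fit time.  Copied tokens
    draw their topic from the source note's current assignments of the same
    word (delta-smoothed) and are excluded from the topic-word counts; see
    the module docstring for the full rules.
    """

    _exclude_copied = True

    def fit(
        self,
        X: RecordCorpus,
        y=None,
        annotation: RedundancyAnnotation | None = None,
        use_python_kernel: bool = False,
    ):
        if annotation is None:
            raise ValueError("RedLDA.fit requires a redundancy annotation")
        return super().fit(
            X, y, annotation=annotation, use_python_kernel=use_python_kernel
        )


def fit_vanilla_lda(
    corpus: RecordCorpus, hyper: HyperParams
) -> tuple[TopicModel, SamplerState]:
    """Functional wrapper over :class:`VanillaLDA`."""
    est = VanillaLDA(
        n_topics=hyper.K,
        alpha=hyper.alpha,
        beta=hyper.beta,
        delta=hyper.delta,
        n_iterations=hyper.n_iterations,
        random_state=hyper.seed,
    ).fit(corpus)
    return est.to_topic_model(), est.state_


def fit_red_lda(
    corpus: RecordCorpus, annotation: RedundancyAnnotation, hyper: HyperParams
) -> tuple[TopicModel, SamplerState]:
    """Functional wrapper over :class:`RedLDA`."""
    est = RedLDA(
        n_topics=hyper.K,
        alpha=hyper.alpha,
        beta=hyper.beta,
        delta=hyper.delta,
        n_iterations=hyper.n_iterations,
        random_state=hyper.seed,
    ).fit(corpus, annotation=annotation)
    return est.to_topic_model(), est.state_


def infer_theta(
    model: TopicModel,
    note: Note | list[int],
    n_iterations: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Fold-in inference of a held-out document's topic mixture.

    phi is held fixed; only the document's assignments are resampled with
    p(k) proportional to (n_dk + alpha) * phi[k, w].  Out-of-vocabulary
    token ids are skipped.  Returns the smoothed theta row after the final
    sweep.
    """
    tokens = note.tokens if isinstance(note, Note) else list(note)
    V = model.vocab_size
    word = np.asarray([t for t in tokens if 0 <= t < V], dtype=np.int32)
    K = model.n_topics
    if len(word) == 0:
        import warnings

        warnings.warn("all tokens out of vocabulary; returning uniform theta")
        return np.full(K, 1.0 / K)
    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=len(word), dtype=np.int32)
    nd = np.bincount(z, minlength=K).astype(np.int64)
    uniforms = rng.random((n_iterations, len(word)))
    if n_iterations > 0:
        fold_in_sweeps(z, word, model.phi, nd, model.alpha, uniforms)
    theta = (nd + model.alpha) / (len(word) + K * model.alpha)
    return theta
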