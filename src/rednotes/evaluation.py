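"""Model evaluation: held-out likelihood, topic coherence, topic alignment.

- Held-out log-likelihood: fold-in Gibbs (phi fixed) infers each test
  document's theta, then the document likelihood is
  sum_i log sum_k theta[k] * phi[k, w_i].
- Topic coherence: the co-document-frequency score over a topic's top
  words, C(t) = sum_{m=2..M} sum_{l<m} log((D(v_m, v_l)+1)/D(v_l)),
  where D counts documents of a reference corpus.  Scores are <= 0; closer
  to zero means the topic's top words actually co-occur.
- Topic alignment: greedy pairing of two models' topics by ascending
  Jensen-Shannon divergence of their word distributions.

Natural logarithms throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .baselines import delete_doc_transform, delete_word_transform
from .corpus import Note, RecordCorpus
from .models import HyperParams, TopicModel, fit_red_lda, fit_vanilla_lda, infer_theta
from .redundancy import RedundancyAnnotation

__all__ = [
    "EvalReport",
    "TopicAlignment",
    "heldout_loglikelihood",
    "topic_coherence",
    "js_divergence",
    "align_topics",
    "compare_methods",
    "METHODS",
]


@dataclass
class EvalReport:
    """Held-out likelihood summary for one model."""

    total_loglik: float
    per_token_loglik: float
    n_tokens: int
    n_oov_skipped: int
    per_note_loglik: list[float] = field(default_factory=list)


def heldout_loglikelihood(
    model: TopicModel,
    test_notes: list[Note],
    n_fold_iterations: int = 50,
    seed: int = 0,
) -> EvalReport:
    """Log-likelihood of held-out notes under a trained model.

    Each note's theta is inferred by fold-in Gibbs with the model's phi
    fixed; out-of-vocabulary tokens are skipped (and counted).
    """
    if not test_notes:
        raise ValueError("empty test set")
    V = model.vocab_size
    total, n_tok, n_oov = 0.0, 0, 0
    per_note = []
    for i, note in enumerate(test_notes):
        tokens = [t for t in note.tokens if 0 <= t < V]
        n_oov += len(note.tokens) - len(tokens)
        if not tokens:
            per_note.append(0.0)
            continue
        theta = infer_theta(
            model, tokens, n_iterations=n_fold_iterations, seed=seed + i
        )
        probs = theta @ model.phi[:, tokens]
        ll = float(np.log(probs).sum())
        per_note.append(ll)
        total += ll
        n_tok += len(tokens)
    if n_tok == 0:
        raise ValueError("no in-vocabulary tokens in the test set")
    return EvalReport(
        total_loglik=total,
        per_token_loglik=total / n_tok,
        n_tokens=n_tok,
        n_oov_skipped=n_oov,
        per_note_loglik=per_note,
    )


def topic_coherence(
    model: TopicModel, reference_corpus: RecordCorpus, top_m: int = 20
) -> np.ndarray:
    """Per-topic co-document-frequency coherence scores.

    Documents are the notes of the reference corpus.  Words that occur in
    no reference document are excluded from a topic's top list (the next
    ranked word is promoted).
    """
    if top_m < 2:
        raise ValueError("top_m must be >= 2")
    # doc-frequency sets per word id
    doc_sets: dict[int, set[int]] = {}
    for di, note in enumerate(reference_corpus.iter_notes()):
        for w in set(note.tokens):
            doc_sets.setdefault(w, set()).add(di)

    scores = np.zeros(model.n_topics)
    for t in range(model.n_topics):
        ranked = np.argsort(model.phi[t])[::-1]
        top = [int(w) for w in ranked if w in doc_sets][:top_m]
        if len(top) < top_m:
            warnings.warn(
                f"topic {t}: only {len(top)} of {top_m} top words occur in "
                "the reference corpus"
            )
        c = 0.0
        for m in range(1, len(top)):
            for l in range(m):
                d_l = len(doc_sets[top[l]])
                d_ml = len(doc_sets[top[m]] & doc_sets[top[l]])
                c += np.log((d_ml + 1) / d_l)
        scores[t] = c
    return scores


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence (natural log), in [0, ln 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    return float(jensenshannon(p, q) ** 2)


@dataclass
class TopicAlignment:
    """Greedy topic pairing between two models."""

    pairs: list[tuple[int, int, float]]
    unmatched_a: list[int]
    unmatched_b: list[int]
    threshold: float


def align_topics(
    model_a: TopicModel, model_b: TopicModel, threshold: float | None = None
) -> TopicAlignment:
    """Pair topics of two models by ascending JS divergence of phi rows.

    Greedy matching: repeatedly accept the lowest-divergence unpaired
    (topic_a, topic_b) pair with divergence <= threshold (default half of
    the ln 2 upper bound).
    """
    if model_a.vocab_size != model_b.vocab_size:
        raise ValueError("models must share a vocabulary")
    if threshold is None:
        threshold = 0.5 * np.log(2)
    Ka, Kb = model_a.n_topics, model_b.n_topics
    jsd = np.empty((Ka, Kb))
    for i in range(Ka):
        for j in range(Kb):
            jsd[i, j] = js_divergence(model_a.phi[i], model_b.phi[j])

    order = np.dstack(np.unravel_index(np.argsort(jsd, axis=None), jsd.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for i, j in order:
        i, j = int(i), int(j)
        if jsd[i, j] > threshold:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j, float(jsd[i, j])))
        used_a.add(i)
        used_b.add(j)
    return TopicAlignment(
        pairs=pairs,
        unmatched_a=[i for i in range(Ka) if i not in used_a],
        unmatched_b=[j for j in range(Kb) if j not in used_b],
        threshold=float(threshold),
    )


def _fit_method(
    method: str,
    corpus: RecordCorpus,
    annotation: RedundancyAnnotation,
    hyper: HyperParams,
) -> TopicModel:
    if method == "vanilla":
        return fit_vanilla_lda(corpus, hyper)[0]
    if method == "redlda":
        return fit_red_lda(corpus, annotation, hyper)[0]
    if method == "deletedoc":
        return fit_vanilla_lda(delete_doc_transform(corpus, annotation), hyper)[0]
    if method == "deleteword":
        return fit_vanilla_lda(delete_word_transform(corpus, annotation), hyper)[0]
    raise ValueError(f"unknown method {method!r}")


METHODS = ("vanilla", "deletedoc", "deleteword", "redlda")


def compare_methods(
    corpus: RecordCorpus,
    annotation: RedundancyAnnotation,
    test_notes: list[Note],
    hyper: HyperParams,
    methods: tuple[str, ...] = METHODS,
    n_runs: int = 3,
    seed: int = 0,
    top_m: int = 20,
    n_fold_iterations: int = 50,
) -> pd.DataFrame:
    """Train each method ``n_runs`` times and tabulate the metrics.

    Per-run seeds are derived deterministically from ``seed`` and the run
    index (shared across methods, so run r of every method starts from the
    same stream).  Returns a DataFrame with per-method mean and standard
    deviation of the held-out per-token log-likelihood and the mean
    coherence over topics and runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for method in methods:
        logliks, coherences = [], []
        for r in range(n_runs):
            run_seed = (seed + 1000003 * (r + 1)) % (2**31)
            h = HyperParams(
                K=hyper.K,
                alpha=hyper.alpha,
                beta=hyper.beta,
                delta=hyper.delta,
                n_iterations=hyper.n_iterations,
                seed=run_seed,
            )
            model = _fit_method(method, corpus, annotation, h)
            rep = heldout_loglikelihood(
                model, test_notes, n_fold_iterations=n_fold_iterations, seed=run_seed
            )
            logliks.append(rep.per_token_loglik)
            coherences.append(float(np.mean(topic_coherence(model, corpus, top_m))))
        rows.append(
            {
                "method": method,
                "mean_loglik": float(np.mean(logliks)),
                "std_loglik": float(np.std(logliks)),
                "mean_coherence": float(np.mean(coherences)),
            }
        )
    return pd.DataFrame(rows).set_index("method")
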