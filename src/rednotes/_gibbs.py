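"""Collapsed Gibbs sweep kernels.

The numba kernel is the production path; ``gibbs_sweeps_py`` is a pure
Python mirror with the identical arithmetic and draw sequence, kept for
cross-validation in the test suite (the two must agree bit-for-bit).

Token layout: all tokens of the corpus are flattened into parallel arrays
in *visit order* (clusters in corpus order, the record's source note first,
then the remaining notes; tokens in position order).  ``src_ptr``/``src_idx``
form a CSR map from each token to the flat positions of its word's
occurrences in its record's source note (empty for non-copied tokens).

Count conventions (the redundancy-aware exclusion rule):
- every token contributes to its own document's topic counts ``n_dk``;
- only ``counted`` tokens contribute to the topic-word counts ``n_kw``/``n_k``
  (under the redundancy-aware model, copied tokens have ``counted=False``);
- copied tokens whose word occurs in the source note draw their topic from
  the source note's current assignments of that word, delta-smoothed;
  copied tokens whose word is absent from the source fall back to the
  standard conditional over the exclusion-filtered counts.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweeps(
    z,
    word,
    doc_of,
    counted,
    is_copied,
    src_ptr,
    src_idx,
    n_dk,
    n_kw,
    n_k,
    alpha,
    beta,
    delta,
    uniforms,
):
    n_sweeps, n_tokens = uniforms.shape
    K, V = n_kw.shape
    p = np.empty(K, dtype=np.float64)
    for s in range(n_sweeps):
        for t in range(n_tokens):
            k_old = z[t]
            d = doc_of[t]
            w = word[t]
            n_dk[d, k_old] -= 1
            if counted[t]:
                n_kw[k_old, w] -= 1
                n_k[k_old] -= 1

            lo = src_ptr[t]
            hi = src_ptr[t + 1]
            if is_copied[t] and hi > lo:
                for k in range(K):
                    p[k] = delta
                for j in range(lo, hi):
                    p[z[src_idx[j]]] += 1.0
            else:
                for k in range(K):
                    p[k] = (
                        (n_dk[d, k] + alpha)
                        * (n_kw[k, w] + beta)
                        / (n_k[k] + V * beta)
                    )

            total = 0.0
            for k in range(K):
                total += p[k]
            r = uniforms[s, t] * total
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += p[k]
                if r < acc:
                    k_new = k
                    break

            z[t] = k_new
            n_dk[d, k_new] += 1
            if counted[t]:
                n_kw[k_new, w] += 1
                n_k[k_new] += 1


def gibbs_sweeps_py(
    z,
    word,
    doc_of,
    counted,
    is_copied,
    src_ptr,
    src_idx,
    n_dk,
    n_kw,
    n_k,
    alpha,
    beta,
    delta,
    uniforms,
):
    """Pure Python mirror of :func:`gibbs_sweeps` (same draws, same floats)."""
    n_sweeps, n_tokens = uniforms.shape
    K, V = n_kw.shape
    p = [0.0] * K
    for s in range(n_sweeps):
        for t in range(n_tokens):
            k_old = int(z[t])
            d = int(doc_of[t])
            w = int(word[t])
            n_dk[d, k_old] -= 1
            if counted[t]:
                n_kw[k_old, w] -= 1
                n_k[k_old] -= 1

            lo, hi = int(src_ptr[t]), int(src_ptr[t + 1])
            if is_copied[t] and hi > lo:
                for k in range(K):
                    p[k] = delta
                for j in range(lo, hi):
                    p[int(z[int(src_idx[j])])] += 1.0
            else:
                for k in range(K):
                    p[k] = (
                        (n_dk[d, k] + alpha)
                        * (n_kw[k, w] + beta)
                        / (n_k[k] + V * beta)
                    )

            total = 0.0
            for k in range(K):
                total += p[k]
            r = uniforms[s, t] * total
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += p[k]
                if r < acc:
                    k_new = k
                    break

            z[t] = k_new
            n_dk[d, k_new] += 1
            if counted[t]:
                n_kw[k_new, w] += 1
                n_k[k_new] += 1


@njit(cache=True)
def fold_in_sweeps(z, word, phi, nd, alpha, uniforms):
    """Fold-in inference for one held-out document with phi fixed.

    ``nd`` is the document's topic count vector (updated in place);
    conditional is p(k) proportional to (nd[k] + alpha) * phi[k, w].
    """
    n_sweeps, n_tokens = uniforms.shape
    K = phi.shape[0]
    p = np.empty(K, dtype=np.float64)
    for s in range(n_sweeps):
        for t in range(n_tokens):
            k_old = z[t]
            nd[k_old] -= 1
            w = word[t]
            total = 0.0
            for k in range(K):
                p[k] = (nd[k] + alpha) * phi[k, w]
                total += p[k]
            r = uniforms[s, t] * total
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += p[k]
                if r < acc:
                    k_new = k
                    break
            z[t] = k_new
            nd[k_new] += 1
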