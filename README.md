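# rednotes

Redundancy-aware topic modeling for clustered note collections.

Clinical notes inside one patient record are highly redundant: clinicians
routinely copy text from an earlier note and paste it into a new one.
Latent Dirichlet Allocation (LDA) assumes every token is an independent
draw from the document's topic mixture, so pasted spans double-count
particular realized words and distort both the learned topic–word
distribution φ and the document mixtures θ. `rednotes` is for text-mining
researchers and clinical-NLP practitioners who want to model such corpora
without throwing data away. It provides:

- **Red-LDA** — a collapsed Gibbs sampler in which tokens flagged as copied
  from the record's *source note* (the longest note) draw their topic from
  the source note's current assignments of the same word and are excluded
  from the topic–word counts;
- **fingerprint preprocessing** — winnowed token *k*-gram hashing that
  locates verbatim shared spans between each note and its record's source
  note and produces per-token copied flags with source alignment;
- the two elimination baselines **DeleteDoc-LDA** (keep only each record's
  source note) and **DeleteWord-LDA** (strip the copied tokens);
- **evaluation**: held-out log-likelihood via fold-in Gibbs, co-document
  frequency topic coherence, Jensen–Shannon topic alignment, Smith–Waterman
  corpus similarity profiling;
- a **synthetic generator** that emulates clustered redundant corpora with
  exact per-token ground truth, for end-to-end testing and parameter
  recovery studies.

## The model

Standard collapsed Gibbs sampling resamples each token's topic from

```
p(z_i = k | ·) ∝ (n_dk + α) · (n_kw + β) / (n_k + V β)
```

with document–topic counts `n_dk`, topic–word counts `n_kw`, topic totals
`n_k`, vocabulary size `V`, and symmetric Dirichlet priors α, β.

Red-LDA partitions each record's tokens. Source-note tokens and non-copied
tokens use the conditional above, computed over **redundancy-excluded**
counts (copied tokens never enter `n_kw`/`n_k`). A copied token of word `w`
instead samples

```
p(z_i = k | ·) ∝ n_src(w, k) + δ
```

where `n_src(w, k)` counts the occurrences of `w` currently assigned to
topic `k` in the record's source note and δ ∈ (0, 1) is a smoothing
constant. If the flagged word does not occur in the source note (detector
mismatch), the token falls back to the standard conditional over the
excluded counts. Copied tokens still count toward their own note's `n_dk`,
so the copying note's mixture feels the source's topics, but φ is
estimated from non-copied tokens only — the exclusion that stops pasted
text from inflating a word's weight in its topic. With no flagged tokens
the sampler reduces *bit-exactly* to vanilla LDA under the same seed.

## Worked example

```python
from rednotes import GeneratorConfig, generate_corpus, annotate_corpus, redundancy_fraction
from rednotes.models import RedLDA

corpus, ann, truth = generate_corpus(
    GeneratorConfig(n_records=20, copy_fraction=(0.4, 0.6), seed=7))
print("notes:", corpus.n_notes, "tokens:", corpus.n_tokens)

det = annotate_corpus(corpus)          # fingerprint detector
print("detected copied fraction of note (r0000, n01):",
      round(redundancy_fraction(det, "r0000", "n01"), 3))

model = RedLDA(n_topics=5, alpha=0.5, n_iterations=300,
               random_state=0).fit(corpus, annotation=det)
print("top words of topic 0:",
      [w for w, _ in model.to_topic_model().top_words(0, 5)])
```

prints

```
notes: 80 tokens: 12824
detected copied fraction of note (r0000, n01): 0.56
top words of topic 0: ['w0195', 'w0058', 'w0118', 'w0137', 'w0105']
```

The generated record `r0000`'s note `n01` pasted ~56 % of its tokens from
its record's source note, and the detector located them; `RedLDA.fit`
learned 5 topics whose top words are the synthetic vocabulary terms each
topic concentrates on.

The method comparison used throughout the tests is one call:

```python
from rednotes.experiments import redundancy_benchmark
print(redundancy_benchmark(seeds=(0, 1, 2), with_coherence=True).round(4))
```

```
            mean_loglik  std_loglik  mean_recovery  mean_coherence
method
vanilla         -3.7517      0.0452         0.0121        -14.4337
deletedoc       -3.7632      0.0448         0.0166        -14.7575
deleteword      -3.7479      0.0471         0.0089        -13.8538
redlda          -3.7485      0.0458         0.0127        -14.8961
```

Columns: mean and standard deviation over seeds of the per-token held-out
log-likelihood (higher is better), mean matched Jensen–Shannon divergence
between learned and generating topics (lower is better), and mean topic
coherence (closer to 0 is better). See `docs/methods.md` for what these
synthetic conditions do and do not show.

There is also a CLI for file-based pipelines:

```bash
rednotes simulate --out sim --n-records 50 --seed 1
rednotes preprocess --input sim/corpus.jsonl --out sim/ann.jsonl
rednotes train --input sim/corpus.jsonl --annotation sim/ann.jsonl \
    --method redlda --k 5 --iters 500 --out model/
rednotes compare --input sim/corpus.jsonl --annotation sim/ann.jsonl --runs 3
```

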