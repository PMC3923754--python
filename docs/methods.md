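# Methods

## Problem setting

A *record corpus* is a set of records (clusters), each a set of notes
written about the same entity — the motivating case is a patient record,
where later notes paste verbatim spans from earlier ones. Redundancy here
is string-level: a span of tokens in one note that appears verbatim in the
record's designated *source note*. The package detects those spans, models
them inside LDA, and evaluates the result.

## Source note and fingerprint detection

Each record designates one source note: the longest note, ties broken by
earliest note id. Other selection rules (timestamps, centroid distance)
are plausible but not implemented.

Copied spans are found only between a note and its record's source note
(not all note pairs), matching the model's assumption that copies
originate from one source per record. Detection is fingerprint-based:

- token *k*-grams (default k = 8) are hashed with a fixed polynomial hash;
- a winnowing pass keeps, in each sliding window of `window` consecutive
  k-gram hashes (default 4), the rightmost minimal hash as a fingerprint;
- every fingerprint of the copying note is looked up in an index of *all*
  source-note k-grams, verified literally, and extended left and right to
  a maximal exact token run;
- runs of at least `min_span` tokens (default 10) are kept; overlapping
  candidates are resolved greedily (longest first, then leftmost in the
  copy, then leftmost in the source), and surviving runs set per-token
  `copied` flags with the aligned source position.

The window is internally clamped to `min_span − k + 1` so that every
shared run of at least `min_span` tokens contains at least one selected
fingerprint: a run of length L has L − k + 1 k-grams, and winnowing
selects one per window. This makes detection of qualifying runs exact, and
the test suite verifies agreement with a brute-force maximal
common-substring oracle. Character-level alignment and cross-record
detection are out of scope; flags are token-level so they align 1:1 with
the sampler.

Corpus redundancy is profiled with token-level Smith–Waterman local
alignment (match +1, mismatch −1, gap −1, via Biopython's pairwise
aligner), normalized by the perfect-alignment score of the shorter note.

## Samplers

Both samplers are collapsed Gibbs with symmetric priors, a single long
chain, and last-sample point estimates
(φ_kw = (n_kw + β)/(n_k + Vβ), θ_dk = (n_dk + α)/(N_d + Kα)), in the style
of the classic reference implementations. Sweep order is canonical for
both models — clusters in corpus order, the record's source note first,
then the remaining notes — so copied tokens always sample against the
source's current (same-sweep) assignments, and the redundancy-aware
sampler reduces bit-exactly to vanilla LDA on an empty annotation under
the same seed. Topic draws use inverse-CDF sampling on the normalized
conditional with one seeded generator; the numba kernel and its
pure-Python mirror produce bit-identical trajectories.

Redundancy-aware rules (see README for formulas): copied tokens sample
from the source note's per-word topic counts with δ smoothing, are
excluded from n_kw/n_k, and still increment their own note's n_dk (N_d
counts all tokens). When a flagged word is absent from the source note the
standard conditional over the excluded counts is used.

### Parameters

| parameter | default | meaning |
|---|---|---|
| K (`n_topics`) | 50 | topics; 50 reflects the scale used for real clinical corpora |
| α | 50/K | symmetric document–topic prior (dimensionless pseudo-counts per topic) |
| β | 0.01 | symmetric topic–word prior |
| δ | 0.1 | pseudo-count added per topic when a copied token samples from source occurrences |
| `n_iterations` | 2000 | full Gibbs sweeps |
| k / window / min_span | 8 / 4 / 10 | fingerprint k-gram length, winnowing window, minimal flagged run (tokens) |
| `max_test_redundancy` | 0.15 | maximal copied fraction for a note to be certified non-redundant for held-out use |

δ = 0.1 rather than a larger value because δ adds K·δ pseudo-counts to a
source note's typically 1–3 occurrences of a copied word; with K = 5,
δ = 0.5 would put more than half of the sampling mass off the source's
actual assignments, defeating the purpose of source-coupled sampling.

## Evaluation

- **Held-out log-likelihood.** Fold-in Gibbs: φ fixed, the held-out note's
  assignments resampled with p(k) ∝ (n_dk + α)·φ_kw for 50 sweeps (the
  default), then ℓ = Σ_i log Σ_k θ_k φ_k,w_i. Fold-in is the cheapest
  estimator consistent with "produce topic assignments for held-out
  documents"; left-to-right and Chib-style estimators are out of scope, so
  absolute values are comparable only within this package.
- **Topic coherence.** C(t) = Σ_{m=2..M} Σ_{l<m} log((D(v_m,v_l)+1)/D(v_l))
  over the topic's top M = 20 words by φ, with document frequencies D from
  the training corpus (documents = notes); words absent from the reference
  corpus are dropped and the next-ranked word promoted. Scores are ≤ 0.
- **Topic alignment.** Greedy pairing on ascending Jensen–Shannon
  divergence (natural log; scipy) of φ rows, accepting pairs with
  JSD ≤ ½·ln 2 by default. Greedy, not optimal, matching: deterministic and
  adequate at K = 50; the test suite confirms it matches exhaustive
  matching on small cases.
- Natural logarithms everywhere.

Held-out notes are chosen per record as the note with the lowest copied
fraction, admitted only if that fraction is ≤ `max_test_redundancy`
(0.15) — the interpretation adopted for certifying held-out documents as
non-redundant; test records are disjoint from training records.

## Synthetic generator

`generate_corpus` follows the redundancy-aware generative story exactly:
φ rows ~ Dirichlet(β·1_V) (generator default β = 0.05, α = 0.5); each
record's source note is plain LDA output; each other note draws its own
θ ~ Dirichlet(α·1_K) for non-copied tokens and pastes contiguous spans
(span length 20–50 tokens by default) from uniformly random source
offsets until a per-note target copied fraction (default range 0.2–0.4,
mean ≈ 0.3 — the redundancy level reported for real patient-record
corpora) is reached; copied tokens carry the source tokens' topic
assignments. Source-note lengths (150–250) dominate the other notes'
(clamped below the source length) so the longest-note rule always
identifies the generative source. A `retain_source_topics=False` switch
relabels copied tokens with topics drawn from the copying note's own
mixture (words still verbatim) for robustness experiments.

What the generator does *not* emulate: clinical vocabulary and note
structure, timestamps, cross-record boilerplate, heavy-tailed
notes-per-record distributions, near-duplicate (edited) rather than
verbatim copies, and correlation between the notes' topic mixtures within
a record. Passing tests therefore demonstrate correctness of the
machinery and behaviour under the model's own assumptions, not performance
on real clinical text.

## Benchmark experiment

`rednotes.experiments.redundancy_benchmark` generates 75 records (4 notes
each, copied fraction 0.4–0.6) per seed, holds out the least-redundant
note of 25 records (≈ the 25 % held-out patient fraction of realistic
protocols), trains the four methods on the remaining 50 records (K = 5,
V = 200, 500 sweeps — sizes chosen so the full comparison runs in seconds
on one CPU), and reports per-token held-out log-likelihood, recovery
(mean matched JSD between learned and generating topics), and coherence.
Fits use α = 0.5, matching the generator's document prior, as is standard
in parameter-recovery studies.

Observed behaviour under these conditions: the redundancy-aware model and
DeleteWord-LDA beat vanilla LDA and DeleteDoc-LDA on held-out likelihood;
an oracle computation with ground-truth assignments confirms that
excluding copied tokens from the topic–word counts lowers φ error
(duplicated tokens act as weight-2 observations and only add variance).
On *topic recovery*, DeleteWord-LDA is the strongest method here and the
redundancy-aware model is close to vanilla. This is a direct consequence
of the generator's assumptions: each note's mixture is drawn
independently, so the copied tokens' (source-derived) topics that Red-LDA
counts into the copying note's n_dk are uninformative for that note's own
mixture, a noise source DeleteWord avoids while sharing the same excluded
topic–word counts. In real records — where notes of one patient share
content and mixtures, record sizes are heavy-tailed, and deleting words
leaves mutilated documents — keeping all tokens while discounting copies
is exactly where the redundancy-aware design is intended to pay off; the
independent-mixture generator cannot exhibit that regime.

## Numerical and degenerate-input choices

- One `numpy` generator seeded per fit drives initialization and all
  sweeps; uniform draws are pre-generated in 200-sweep blocks (memory
  bound), so runs are bit-reproducible given (corpus, annotation, seed).
- Derived seeds (per run/experiment component) come from SHA-256 of the
  base seed and an index, kept below 2³¹.
- Empty notes after DeleteWord are dropped with a warning (zero-length
  documents are degenerate for LDA); vocabularies are never re-pruned
  after transforms so φ matrices stay comparable across methods.
- Held-out notes with all tokens out of vocabulary get a uniform θ and a
  warning; empty test sets and empty corpora are errors.
- Ties: source selection → earliest note id; span resolution → longest,
  then leftmost; held-out note selection → lowest copied fraction, then
  earliest note id.

## Known limitations

- Single-chain inference without convergence diagnostics; at desk scale,
  chain-to-chain variability is comparable to the method differences the
  benchmark measures (hence means over seeds).
- The fingerprint detector is exact only for verbatim token runs; edited
  copies (insertions/substitutions inside a span) fragment or escape
  detection below `min_span`.
- Hyperparameters are fixed, symmetric, and not optimized during
  sampling.
- The Smith–Waterman profile scores the single best local region per note
  pair, so multi-span redundancy yields lower similarity values than the
  summed copied fraction.
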