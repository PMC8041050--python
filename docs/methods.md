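# Methods

This note documents the models implemented in `diagtutor`, the parameters
that matter, the numerical choices, and what the synthetic data does and
does not establish.

## Concept matching and hypothesis grading

Free text is normalized to a token *set*: lowercased, split on
non-alphanumeric characters, stop words removed (editable list shipped in
`diagtutor/data/stopwords.txt`). No stemming is applied for concept
matching — concept labels are short noun phrases where exact token overlap
is the signal, and stemming would blur distinctions such as
*inflamed/inflammation* that ontology synonym lists already cover.

Each ontology concept is scored by the maximum Jaccard similarity between
the input tokens and the tokens of its label or any synonym; ties are broken
by lexicographically smallest concept id so matching is deterministic and
testable. A match below `min_sim` (default **0.2**, i.e. at least roughly
one token in five shared) is treated as *unrecognized* and triggers a
rephrase prompt; without a floor, arbitrary text would always link to some
concept.

The grading verdict comes from the minimum shortest-path edge count between
the matched concept and any reference hypothesis, computed on the
*undirected* is-a graph (the grading rule counts edges on any connecting
path, regardless of direction). Bands: 0 → correct, 1–4 → close, ≥ 5 or
disconnected → incorrect. Distance exactly 5 is deliberately graded
*incorrect*: the close band is kept exactly at 1–4, and widening it to 5
would be the only alternative reading; the choice is fixed here and covered
by tests. Only is-a edges are traversed; other relationship types are out
of scope. Ancestor queries (used for the "be more specific" feedback) follow
parent links only and are irreflexive.

The engine resolves physical-exam and medical-test requests with this same
Jaccard machinery rather than the sentence encoder: requests are short noun
phrases ("chest x-ray") where token overlap against names and synonyms is
sufficient and fully inspectable.

## Word embeddings

Skip-gram with negative sampling (window 3, 5 negatives, unigram^0.75
noise distribution, linearly decaying learning rate from 0.05, 5 epochs,
dimension default 32), trained by the canonical *sequential* SGD update —
one update per (center, context) sample. Synonym supervision enters two
ways: each declared pair is replayed as extra positive skip-gram samples
(`synonym_boost`, default 10 per epoch and direction) and directly pulled
together in vector space after each epoch (`synonym_pull`, default 0.05).
Both defaults are mild; they reliably place declared synonyms above the
random-pair cosine baseline without collapsing the space. Synonym pairs with
out-of-corpus words are skipped with a logged warning. Training is exactly
reproducible from the seed. The `EmbeddingModel` container is deliberately
plain so pretrained vectors from any source can be swapped in.

## Siamese recurrent matcher

A single-layer LSTM (gates in i, f, g, o order; forget-gate bias initialized
to 1; Glorot-uniform weight ranges) is applied to both questions of a pair —
one parameter set, structurally shared. Questions are tokenized, mapped to
embedding rows (out-of-vocabulary tokens map to a dedicated zero-initialized
*trainable* UNK row), truncated to the first `max_len` tokens (default
**30**) and front-padded; padded steps are masked so they carry the state
through unchanged, which makes front padding equivalent to processing only
the real tokens. The pair score is exp(−‖h₁−h₂‖₁): exactly 1 for identical
hidden states, strictly positive always, symmetric because the branches
share weights.

Training minimizes the mean squared error between the score and the binary
label, with hand-derived backpropagation through time into all weights and
the embedding matrix. Two optimization regimes:

* **≤ 64 pairs:** full-batch gradient descent with a backtracking step size
  (halve on increase, grow 1.1× on success). This guarantees a monotone
  non-increasing per-epoch loss trace, which is the documented sanity
  contract for overfitting small separable sets.
* **larger sets:** minibatch Adam (batch 64, lr default 0.02) with seeded
  shuffling; the trace records mean minibatch loss per epoch.

An early vectorized variant of exp(−L1) training is known to stall when
initial distances are large (score ≈ 0 multiplies every gradient); the
Glorot init plus bounded tanh/σ activations keeps initial scores in a
trainable range, and the overfit test (10 pairs to loss < 0.05) guards the
regime.

The ranker scores every reference question, sorts by descending score with
ties broken by smallest reference id, drops scores **≤** the threshold
(default 0.5 — "exceeds" is strict), and truncates to three. Returning more
than three would leak reference questions the student has not yet thought
of; an empty return is a valid "not understood" outcome. Rank-k accuracy is
evaluated by pure ranking without the threshold, so it is non-decreasing
in k.

## Simulation engine

Sessions enforce free navigation: data-gathering actions stay callable after
analysis actions until the final diagnosis closes the session. Gathered
factors and the differential only grow; only verdict-correct hypotheses
enter the differential. The binary grid spans *student-gathered* factors ×
the differential (information the student has actually collected), not the
full reference factor list. Matched reference questions remain matchable;
re-asking returns the answer again but reveals nothing new.

Pattern-analysis links are checked against the student's *own* submitted
grid (I↔positive, D↔negative, N↔none) — the exercise tests internal
consistency of the student's reasoning; the grid submission already graded
agreement with the reference. The per-hypothesis display score, used to
render the hypothesis node, is invented for display: with weights high = 2
and low = 1, score = (signed sum + weight sum) / (2 × weight sum), i.e. the
positive fraction of weighted evidence, 0.5 when no weighted links exist.

Every operation appends exactly one log entry (timestamp from an injectable
clock, action, input, outcome, feedback code). Replay re-executes the logged
inputs against a fresh session, feeding the recorded timestamps back through
the clock, and reproduces the identical end state, feedback stream and log
bytes — the engine is deterministic given fixed models.

## Tutoring layer

The inner-loop feedback catalog is a closed category → code mapping covering
every engine outcome; unknown categories fail loudly so the catalog cannot
silently drift out of sync with the engine. One code was added beyond the
minimal evidenced set: `hypothesis_rejected`, for a recognized but distant
hypothesis — distinct from `not_understood` (text unrecognized), since the
two situations need different student guidance. The catalog is extensible
via configuration. Review links come from the case file's per-hypothesis
topic → URL map, so any reference service can be plugged in.

The outer-loop summary sorts hypotheses by descending binary-analysis
mistake count (ties by id) and attaches the review links.

## Bayesian Knowledge Tracing

Observations: a hypothesis's binary-analysis performance in one simulation
is discretized to correct iff the fraction of correctly filled cells reaches
`success_fraction` (default **0.8**, i.e. at most one mistake in five
cells) — some aggregation is required to map cell-level grading to the
binary observations BKT consumes, and a high bar keeps "correct" meaningful
on small grids.

The update is the standard two-state form: condition the mastery prior on
the observation (Bayes step with slip/guess emission), then apply the
learning transition. Evidence with probability zero under the model (e.g. a
correct answer with p = 0, p_G = 0) raises an error instead of returning
NaN. Sequence likelihood uses the scaled forward algorithm; it equals the
brute-force sum over all 2^T hidden paths to 1e-10, which the tests verify,
alongside a cross-check against an independent HMM library.

Fitting is EM (forward-backward E-step, closed-form M-step) with the
no-forgetting constraint built into the chain structure, tolerance 1e-6 on
the log-likelihood, at most 200 iterations, and 5 seeded random restarts.
Restarts converging to the label-switched degenerate mode (p_S + p_G ≥ 1)
are discarded; the best valid likelihood wins. Parameters are clipped to
[1e-6, 1−1e-6] to avoid absorbing boundaries. Sequences of mixed length are
grouped by length and their sufficient statistics pooled before each M-step.
Fits are global per skill rather than per student — per-student fits from a
handful of simulations would be hopelessly under-determined. Mastery
threshold default **0.95**; the report lists weakest skills first.

## Synthetic data: what it shows and what it does not

The generators define the test conditions for the whole package. The worked
clinical case reproduces the published three-factor, two-hypothesis teaching
example with its full I/D/N reference grid. The paraphrase benchmark builds
6 simulations × 16 reference questions from 36 question templates (7
phrasing frames × a 3-way synonym slot each); training pairs (default 400,
balanced) are slot-substituted paraphrases (positives) and cross-template or
distractor pairs (negatives); the 96 test questions are realizations never
seen in training. Simulated learners follow the BKT generating process
exactly.

Limits: template paraphrases vary a synonym slot and a phrasing frame, not
word order, ellipsis, typos, or the unbounded variety of real student
English; topics are lexically well-separated, so the benchmark is easier
than a real reference list with several overlapping cardiorespiratory
questions. Accuracy on it demonstrates that the pipeline learns
synonym-invariant sentence matching end to end at desk scale (training plus
evaluation in seconds on one CPU); it does not predict accuracy on real
student questions. Likewise, BKT parameter recovery shows correctness of
the fitter under the model's own assumptions, not that real students follow
a two-state no-forgetting chain.

## Known limitations

* The ontology loader handles desk-scale hierarchies; the RF2 adapter reads
  the standard snapshot column layout but has only been exercised on
  synthetic fixtures, not a licensed release.
* The LSTM is single-layer and CPU-bound by design; very long questions are
  truncated at 30 tokens.
* The feedback catalog covers the engine's outcome categories; richer
  pedagogical messages (severity levels, localization) are configuration
  concerns left to the embedding application.
* No therapy or patient-management phases; the simulation ends at the final
  diagnosis.
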