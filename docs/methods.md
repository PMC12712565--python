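# Methods

## Problem setting

A rubric-scored patient note is a triple: the note's free text, a
case-specific list of clinical features to look for, and expert gold
annotations giving, per feature, zero or more alternative phrasings with
character-offset spans (0-based, half-open; discontinuous segments
allowed). A generative extractor emits one record per requested feature —
extracted text (empty = reported absent) plus per-token probabilities.
The package implements everything around such an extractor: similarity
and bidirectional matching, the confidence-regularized training
objective, the inference-time matching gate, and the evaluation harness.

## Similarity primitives

All comparisons normalize first (lowercase, collapse whitespace runs,
strip). The workhorse is a **single-order character n-gram F1**: clipped
multiset intersection of the two strings' character n-grams (spaces
included), precision over candidate grams, recall over reference grams,
harmonic mean. Defaults and choices:

* **n = 3**, configurable 1–6. A single order (not a multi-order average)
  keeps the score identical to the printed formula it implements; order 3
  balances typo tolerance against accidental matches on short clinical
  phrases.
* Clipped multiset counts rather than set membership, so repeated grams
  ("aaaa") are counted honestly; set semantics available via
  `set_semantics=True`.
* Equal normalized strings score 1 even when shorter than n — otherwise
  exact matches of very short features ("ha") would score 0.
* Symmetry holds by construction: swapping arguments exchanges P and R.

Levenshtein distance is delegated to `edlib` (unit-cost edit distance);
the normalized similarity is `1 − dist/max(len)`. Token overlap is
gold-relative: the fraction of the gold phrase's punctuation-stripped
tokens recovered by the prediction (set semantics, no stop-word list).
TF-IDF cosine uses scikit-learn's smoothed IDF with the package
tokenizer; document frequencies always come from an explicit corpus
argument. Embedding cosine is a *contract* — any `str -> vector`
callable; the bundled deterministic `BagOfWordsEmbedder` (stable MD5
hashing into 512 buckets) stands in wherever a sentence-embedding model
would be plugged in, and is also what the test-suite and the synthetic
evaluation use.

## Confidence pipeline

Token probabilities are aggregated by **geometric mean** — a single
operation that is simultaneously an average and length-normalized (a
constant-probability sequence scores that constant regardless of length);
the arithmetic mean sits behind a flag for sensitivity checks. Longer
features are harder, so confidence is shrunk by `c^(1 + tokens/λ)` with
λ = 20 — identity at zero length, order-preserving, fixed point at c = 1.
The power-law form is this package's choice; the parameter and its role
(a feature-complexity normalizer) are fixed by the framework, the exact
functional form was open. During training, seeded Gaussian noise with
standard deviation β·0.05 (β = 0.2) is added and clipped to
[ε, 1−ε], ε = 1e−4, keeping the confidence distribution from collapsing;
at inference (no RNG supplied) the operation is the identity.

Across epochs, an EMA feedback loop `α·prev + (1−α)·current` with α = 0.7
smooths the corpus-mean confidence, and the penalty-gating threshold τ
follows a linear curriculum from τ_init = 0.6 at epoch 0 to τ_final = 0.7
at the last epoch. An alternative mode couples τ to the previous epoch's
F1 (interpolating on F1 between the same endpoints, clipped); the linear
schedule is the default because the endpoints are the firmly specified
part while the F1 coupling is described only loosely.

## Bidirectional matching and penalties

Forward matching assigns each non-empty prediction its best chrF over all
gold phrasings (independent per-feature argmax — deliberately not a
bipartite assignment); backward matching mirrors this for each present
gold feature, taking the best alternative phrasing. Penalty bases:

* hallucination: `0.7·(1−F1)` when F1 > 0.3 (partial credit), else the
  full `1−F1`; the comparison is strict, so F1 = 0.3 takes the full
  branch;
* omission: gold features with backward F1 < 0.5 (strict) contribute
  `1−F1`.

The omission aggregation is the **mean over all present gold features**
(`mean_all`), so a note's penalty scales with the fraction of its rubric
missed; `mean_missing` and `sum` are available as config switches since
the aggregation was an open design point.

The overconfidence penalty composes base and confidence as
`base·(c + α·(c−τ)²)` with α = 2, zero when c ≤ τ or base = 0. This form
satisfies every stated constraint — proportional to confidence, quadratic
above the threshold, gated to overconfident incorrect predictions — and
is the single documented choice; a pure-quadratic variant
(`base·α·(c−τ)²`) sits behind `penalty_form`. It is continuous in c on
c > τ, increasing in c, and never increases when τ rises (curriculum
monotonicity).

Per note, the hallucination penalty is the mean of per-prediction
penalties and the total loss is the exact linear form
`CE + 0.2·hallucination + 0.5·missing`; omissions weigh more because a
first-phase extractor typically under-recalls. `LossBreakdown.no_penalty_gradient`
encodes the gradient contract: a differentiable generator embedding this
objective must skip the penalty backward pass when both penalties are
zero. The mock path asserts the flag only. Cross-entropy is accepted as a
per-note scalar (the mock generator has none); combining per-token versus
per-batch was unspecified and per-note batching is the choice here.

## Matching gate

Three validation steps in fixed order, first success wins, all offsets
into the original note text, ties broken leftmost-then-shortest:

1. **exact** — case-insensitive whitespace-flexible regex search; failing
   that, the best token-aligned window (sizes k−1…k+1 around the
   extraction's k tokens, punctuation-stripped boundaries) with
   normalized Levenshtein ≥ 0.85;
2. **sentence** — sentences split on `. ; ! ?` and newlines (rule-based:
   clinical notes are choppy and a sentence model would be a heavy
   dependency); best sentence by TF-IDF cosine with the note's own
   sentences as the corpus, accepted at ≥ 0.5, evidence = covering
   intervals of the extraction-token runs inside that sentence (possibly
   discontinuous);
3. **windowed** — sliding window of `len(tokens)+2` note tokens, scored
   by the fraction of extraction tokens covered, accepted at ≥ 0.5,
   evidence = covering interval of the matched tokens.

All four thresholds (0.85 / 0.5 / 0.5 / slack 2) are this package's
defaults — the three-step structure is fixed by the framework, the
numbers were not published — and each is a `GateConfig` knob. Empty
extraction text is rejected with method `none`. Validated decisions
always carry spans that reconstruct their matched text, asserted by the
test suite on every synthetic corpus run.

## Evaluation

Two presence pipelines, never mixed. **Binary overlap**: a feature is
found when ≥ 50% of the gold phrase's tokens appear in the
gate-validated prediction (best alternative phrasing; gold-relative
denominator). **Semantic**: embedding cosine between extracted text and
the rubric description, present at ≥ 0.5, borderline on [0.5, 0.7] — the
borderline items plus all misses form the manual-review queue, ordered by
ascending similarity. Gate rejection takes precedence in both modes: a
rejected extraction never asserts presence.

P/R/F1 use standard conventions (all 0 with gold but no predictions; all
1 with neither). Calibration is computed on *continuous* feature-level
chrF scores, not binary outcomes: ECE is the count-weighted mean absolute
gap between bin-mean confidence and bin-mean score over the four bins
0.6–0.7 … 0.9–1.0, with an extra underflow bin [0, 0.6) included by
default (the four published bins leave low confidence unmapped;
`underflow=False` mirrors them exactly). The reliability table reports
both the signed gap (score − confidence) and the gap-to-optimum
(score − 1). Brier is the mean squared confidence–score gap.

The error ledger counts hallucinations (presence false positives, plus —
by default — asserted-but-gate-rejected extractions when gate outcomes
are supplied) and omissions (false negatives), with rates and pairwise
percent reductions rounded half-up to one decimal as printed in
comparative reports; raw counts are retained. Paired comparisons
bootstrap the F1 difference at the **note** level (resampling notes, the
natural exchangeable unit of a test set) with a percentile 95% CI, and
run McNemar on the per-feature correctness discordance table — exact
two-sided binomial below 25 discordant pairs, continuity-corrected
chi-square above.

## Synthetic data

`generate_corpus` emulates the structure of the real task: 10 cases ×
10 notes × 12 rubric features by default, each feature present with
probability 0.7, written into the note as its canonical phrase, a
paraphrase (p = 0.3), a negated variant (p = 0.1) and/or a single-edit
typo (p = 0.1), with filler sentences interspersed. Gold spans are the
exact offsets of the inserted surface forms, so the span-reconstruction
invariant holds by construction, and identical configs yield
byte-identical corpora. Typos are single edit operations, guaranteeing
the gate's Levenshtein path is exercised.

The mock extractor misses present features with probability 0.209 and
fabricates absent ones with probability 0.117 per feature — the error
levels of an untuned few-shot extractor on this task — decaying by 0.5
per epoch to emulate regularization training. Confidences are Beta
distributed: Beta(10.5, 2) for correct outputs (mean ≈ 0.84, matching
the stable confidence level this framework is designed around) and
Beta(5, 2) for fabrications, so confidence separates the two populations
and the overconfidence penalty has signal to work with. Note the
denominator convention: the mock's `hallucination_rate` is a per-absent-
feature fabrication probability, while ledger rates divide by all
features of a corpus — corpus-level rates are therefore smaller by the
absent-feature share.

What the synthetic data does **not** emulate: realistic clinical
language, abbreviation/negation semantics, annotation disagreement,
multiple gold alternatives per feature, or any correlation between
feature difficulty and extractor errors. Passing tests therefore
demonstrate the correctness of the machinery under controlled error
structure, not clinical performance; headline published figures (F1,
ECE/Brier trajectories on real notes) require the original dataset and a
trained model, which are out of scope here.

## Problem sizes and numerical choices

The default test corpora range from 3×4×6 (unit tests) to 10×25×40
(binomial presence check, 10⁴ pairs); rate-recovery runs use ≈ 2000
(note, feature) pairs, giving 3·SE bands of a few percentage points; the
training emulation runs 5 epochs × 100 notes. Bootstrap uses 2000–10 000
replicates. All randomness flows through `numpy.random.default_rng` with
explicit seeds; noise injection clips to [1e−4, 1−1e−4]; comparisons at
the 0.3/0.5 penalty cuts are strict exactly as specified; reported
rates/reductions round half-up via `decimal` (banker's rounding would
disagree on exact halves).

## Known limitations

* The gate's sentence step refits a TF-IDF vectorizer per extraction
  (quadratic in sentence count); fine at note scale, not tuned for bulk
  corpora.
* Multiple gold alternatives are scored by the best-scoring phrasing
  everywhere; no attempt to enforce consistency across features.
* The embedding contract ships only the bag-of-words stand-in; semantic
  evaluation quality with a real sentence embedder will differ (the
  stand-in is blind to synonymy, so paraphrased extractions score 0).
* `run_epoch` emulates training dynamics through the mock's decaying
  error schedule; it does not optimize anything.
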