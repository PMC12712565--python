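# notegate

Confidence-regularized clinical feature extraction: the computational
machinery for training and evaluating generative extractors that read
free-text patient notes (e.g. USMLE Step-2 CS examination notes) against
case-specific rubrics of clinical features, while keeping two failure
modes under control — **hallucinated features** (asserted but unsupported
by the note) and **missing features** (documented but not extracted).

The package is model-agnostic: the LLM itself is an abstract generator
contract, and a seeded mock extractor plus a synthetic note generator make
every component testable end to end with no clinical data and no GPU.

## Who it is for

Researchers in clinical NLP and medical-education assessment who need:

* the matching/penalty machinery of confidence-regularized fine-tuning,
  without committing to a particular model or training stack;
* an inference-time **matching gate** that only validates extractions
  locatable in the note text (with character-offset evidence spans);
* a complete evaluation harness: binary-overlap and semantic presence
  scoring, precision/recall/F1, calibration (ECE, Brier, reliability
  tables), error accounting with percent reductions, and paired
  significance tests (note-level bootstrap, McNemar).

## The model

For one note with predicted features e₁…eₙ and expert gold g₁…gₙ
(gᵢ = ∅ when absent), similarity is the single-order character n-gram F1

    F1ₙ(e, g) = 2PR / (P + R),   P = |N(e) ∩ N(g)| / |N(e)|,  R = |N(e) ∩ N(g)| / |N(g)|

with clipped-multiset intersection of character n-grams (default n = 3).
Bidirectional matching takes, for every prediction, its best F1 over all
gold features (*forward*; hallucination side) and, for every gold feature,
its best F1 over all predictions (*backward*; omission side):

* hallucination base: `0.7·(1 − F1)` when F1 > 0.3, else the full `1 − F1`;
* a gold feature with backward F1 < 0.5 counts as missing, contributing
  `1 − F1` (averaged over all gold features of the note).

Each prediction carries a confidence c — the geometric mean of its token
probabilities, shrunk for long features by `c^(1 + len/λ)` (λ = 20) and,
during training, perturbed by seeded Gaussian noise with SD β·0.05
(β = 0.2). Only *overconfident incorrect* predictions are penalized: with
dynamic threshold τ (rising 0.6 → 0.7 over training) and α = 2,

    penalty = base · (c + α·(c − τ)²)   if c > τ and base > 0, else 0.

The training objective is `total = CE + 0.2·hallucination + 0.5·missing`
(omissions weighted heavier); when both penalties vanish the step reports
`no_penalty_gradient`, the contract that no penalty gradient may be
propagated. An EMA feedback loop (α = 0.7) smooths confidence across
epochs.

At inference the three-step matching gate validates each extraction
against the note: (1) exact/regex matching with a Levenshtein fallback for
misspellings, (2) sentence-level TF-IDF similarity with token-run
alignment, (3) windowed token-overlap matching — first success wins, with
evidence offsets into the original text.

## Worked example

```python
from notegate.corpus import Extraction, GoldAnnotation, PatientNote
from notegate.gate import validate
from notegate.objective import note_penalties, total_loss

note = PatientNote("n1", "c1", "denies fever or chills. pt has diarrhea.")
gold = [GoldAnnotation("n1", "f1", ("fever",), (((7, 12),),))]

print(validate("diarhea", note))       # misspelling, still locatable
ext = [Extraction("n1", "f2", "crushing substernal pain", confidence=0.9)]
hall, miss, _ = note_penalties(ext, gold, tau=0.6)
print(round(hall, 3), round(miss, 3))
print(round(total_loss(1.0, hall, miss).total, 3))
```

prints

```
GateDecision(status='validated', method='levenshtein', span=((31, 39),), matched_text='diarrhea')
1.08 1.0
1.716
```

The misspelled extraction "diarhea" is validated by the Levenshtein step
with its evidence span (offsets 31–39 reconstruct "diarrhea"). The
fabricated "crushing substernal pain" shares no trigram with the gold
(base = 1) at confidence 0.9 > τ, giving a hallucination penalty of
0.9 + 2·(0.9 − 0.6)² = 1.08; the unextracted gold "fever" makes the
missing penalty 1.0; the total loss is 1.0 + 0.2·1.08 + 0.5·1.0 = 1.716.

A full synthetic pipeline is available from the shell:

```bash
notegate simulate --out corpus --epochs 5
notegate gate     --notes corpus/notes.csv --features corpus/features.csv \
                  --gold corpus/annotations.csv \
                  --extractions corpus/extractions_epoch4.jsonl --out gated.jsonl
notegate evaluate --mode overlap --notes corpus/notes.csv \
                  --features corpus/features.csv --gold corpus/annotations.csv \
                  --extractions gated.jsonl --out decisions.jsonl
```

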