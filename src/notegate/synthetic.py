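"""Seeded synthetic clinical corpora and a mock extractor.

The generator emulates the structure of rubric-scored examination notes:
a fixed set of clinical cases, each with a per-case rubric of features,
and per-case notes in which each rubric feature is present with a
configured probability. Present features are written into the note as
their canonical phrase, a paraphrase, a negated variant and/or a
single-edit misspelling, and the exact character offsets of the inserted
surface form are recorded as gold spans — so every annotation satisfies
the span-reconstruction invariant by construction.

The mock extractor stands in for the LLM generator: it misses present
features at a configured rate, fabricates absent ones at another, adds
paraphrase noise, and draws feature confidences from separate Beta
distributions for correct versus fabricated extractions (fabrications
are less confident on average, which is what lets the overconfidence
penalty discriminate). An ``epoch_decay`` factor shrinks both error rates
across epochs, emulating a model that improves during regularization
training. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from notegate.corpus import Extraction, FeatureSpec, GoldAnnotation, PatientNote
from notegate.objective import GeneratorContract
from notegate.similarity import tokenize

# (rubric description, canonical phrase, paraphrases, negated variant)
_PHRASE_BANK: list[tuple[str, str, tuple[str, ...], str]] = [
    ("fever", "fever", ("febrile episodes", "elevated temperature"), "denies fever"),
    ("chills", "chills", ("shaking chills", "rigors"), "denies chills"),
    ("chest pain", "chest pain", ("pain in the chest", "chest discomfort"), "denies chest pain"),
    ("shortness of breath", "shortness of breath", ("difficulty breathing", "dyspnea on exertion"), "denies shortness of breath"),
    ("productive cough", "productive cough", ("cough with sputum", "coughing up phlegm"), "denies cough"),
    ("night sweats", "night sweats", ("sweating at night", "drenching sweats"), "denies night sweats"),
    ("headache", "headache", ("pain in the head", "throbbing headache"), "denies headache"),
    ("dizziness", "dizziness", ("feeling lightheaded", "episodes of vertigo"), "denies dizziness"),
    ("nausea", "nausea", ("feeling nauseated", "queasy stomach"), "denies nausea"),
    ("vomiting", "vomiting", ("episodes of emesis", "threw up twice"), "denies vomiting"),
    ("diarrhea", "diarrhea", ("loose stools", "watery bowel movements"), "denies diarrhea"),
    ("constipation", "constipation", ("infrequent bowel movements", "hard stools"), "denies constipation"),
    ("abdominal pain", "abdominal pain", ("pain in the abdomen", "stomach pain"), "denies abdominal pain"),
    ("epigastric discomfort", "epigastric discomfort", ("pain in the upper stomach", "burning in the epigastrium"), "denies epigastric discomfort"),
    ("weight loss", "weight loss", ("unintentional loss of weight", "lost ten pounds"), "denies weight loss"),
    ("loss of appetite", "loss of appetite", ("decreased appetite", "poor appetite lately"), "denies loss of appetite"),
    ("fatigue", "fatigue", ("feeling tired all the time", "low energy"), "denies fatigue"),
    ("back pain", "back pain", ("pain in the lower back", "lumbar discomfort"), "denies back pain"),
    ("joint pain", "joint pain", ("aching joints", "pain in multiple joints"), "denies joint pain"),
    ("muscle weakness", "muscle weakness", ("weakness in the muscles", "generalized weakness"), "denies muscle weakness"),
    ("palpitations", "palpitations", ("racing heartbeat", "heart pounding"), "denies palpitations"),
    ("leg swelling", "leg swelling", ("swelling in both legs", "edema of the ankles"), "denies leg swelling"),
    ("frequent urination", "frequent urination", ("urinating more often", "increased urinary frequency"), "denies frequent urination"),
    ("painful urination", "painful urination", ("burning with urination", "dysuria"), "denies painful urination"),
    ("blood in urine", "blood in urine", ("hematuria", "red colored urine"), "denies blood in urine"),
    ("blood in stool", "blood in stool", ("bloody stools", "rectal bleeding"), "denies blood in stool"),
    ("sore throat", "sore throat", ("throat pain", "pain on swallowing"), "denies sore throat"),
    ("runny nose", "runny nose", ("nasal discharge", "rhinorrhea"), "denies runny nose"),
    ("ear pain", "ear pain", ("pain in the right ear", "otalgia"), "denies ear pain"),
    ("blurred vision", "blurred vision", ("vision is blurry", "trouble focusing vision"), "denies blurred vision"),
    ("numbness in hands", "numbness in hands", ("tingling in the fingers", "hands feel numb"), "denies numbness in hands"),
    ("tremor", "tremor", ("shaking of the hands", "hand tremor at rest"), "denies tremor"),
    ("rash", "rash", ("itchy red rash", "skin eruption"), "denies rash"),
    ("easy bruising", "easy bruising", ("bruises easily", "frequent bruising"), "denies easy bruising"),
    ("trouble sleeping", "trouble sleeping", ("difficulty falling asleep", "poor sleep"), "denies trouble sleeping"),
    ("anxiety", "anxiety", ("feeling anxious", "constant worry"), "denies anxiety"),
    ("depressed mood", "depressed mood", ("feeling down", "low mood for weeks"), "denies depressed mood"),
    ("alcohol use", "alcohol use", ("drinks alcohol daily", "heavy alcohol intake"), "denies alcohol use"),
    ("tobacco use", "tobacco use", ("smokes one pack per day", "current smoker"), "denies tobacco use"),
    ("family history of diabetes", "family history of diabetes", ("mother has diabetes", "diabetes runs in the family"), "no family history of diabetes"),
]

_FILLERS = (
    "vital signs were reviewed",
    "the remainder of the history is unremarkable",
    "symptoms started two weeks ago",
    "no recent travel or sick contacts",
    "medications were reconciled",
    "follow up was discussed",
)

_FABRICATIONS = (
    "zygomatic implosion",
    "retrograde plume sign",
    "glottal cascade episodes",
    "fimbrial resonance",
    "paradoxical lumen flutter",
    "velar crepitus on exertion",
)


@dataclass(frozen=True)
class MockProfile:
    """Error and confidence profile of the mock extractor.

    Default error rates mirror the error levels typical of an untuned
    few-shot extractor on this task (about one in five present features
    missed, about one in nine absent features fabricated); Beta confidence
    defaults put correct extractions near 0.84 mean confidence and
    fabrications lower, so confidence carries signal.
    """

    hallucination_rate: float = 0.117
    miss_rate: float = 0.209
    paraphrase_noise: float = 0.15
    conf_correct: tuple[float, float] = (10.5, 2.0)
    conf_incorrect: tuple[float, float] = (5.0, 2.0)
    epoch_decay: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hallucination_rate", "miss_rate", "paraphrase_noise", "epoch_decay"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for a, b in (self.conf_correct, self.conf_incorrect):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be > 0")


@dataclass(frozen=True)
class SynthConfig:
    """Shape and noise structure of a synthetic corpus."""

    n_cases: int = 10
    notes_per_case: int = 10
    features_per_case: int = 12
    p_feature_present: float = 0.7
    p_paraphrase: float = 0.3
    p_typo: float = 0.1
    p_negation_variant: float = 0.1
    mock: MockProfile = field(default_factory=MockProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "notes_per_case", "features_per_case"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p_feature_present", "p_paraphrase", "p_typo", "p_negation_variant"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _single_edit(text: str, rng: np.random.Generator) -> str:
    """One random insert/delete/substitute of a letter (never a space)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    positions = [i for i, ch in enumerate(text) if ch.isalpha()]
    if not positions:
        return text
    i = positions[rng.integers(len(positions))]
    op = rng.integers(3)
    if op == 0 and len(text) > 3:  # delete
        return text[:i] + text[i + 1 :]
    if op == 1:  # substitute
        repl = letters[rng.integers(26)]
        if repl == text[i]:
            repl = letters[(letters.index(repl) + 1) % 26]
        return text[:i] + repl + text[i + 1 :]
    return text[:i] + letters[rng.integers(26)] + text[i:]  # insert


def generate_corpus(
    cfg: SynthConfig,
) -> tuple[list[PatientNote], list[FeatureSpec], list[GoldAnnotation]]:
    """Generate templated notes with exact gold offsets, fully seeded.

    Raises when ``features_per_case`` exceeds the phrase bank.
    """
    if cfg.features_per_case > len(_PHRASE_BANK):
        raise ValueError(
            f"features_per_case={cfg.features_per_case} exceeds phrase bank "
            f"size {len(_PHRASE_BANK)}"
        )
    rng = np.random.default_rng(cfg.seed)
    notes: list[PatientNote] = []
    features: list[FeatureSpec] = []
    gold: list[GoldAnnotation] = []

    for ci in range(cfg.n_cases):
        case_id = f"case_{ci:02d}"
        bank_idx = rng.choice(len(_PHRASE_BANK), size=cfg.features_per_case, replace=False)
        case_entries = [_PHRASE_BANK[int(i)] for i in bank_idx]
        for fi, (desc, _, _, _) in enumerate(case_entries):
            features.append(FeatureSpec(f"{case_id}_f{fi:02d}", case_id, desc))

        for ni in range(cfg.notes_per_case):
            note_id = f"{case_id}_note_{ni:02d}"
            parts = ["patient presents for evaluation."]
            offset = len(parts[0])
            anns: list[GoldAnnotation] = []
            for fi, (desc, canonical, paraphrases, negation) in enumerate(case_entries):
                feature_id = f"{case_id}_f{fi:02d}"
                present = rng.random() < cfg.p_feature_present
                if not present:
                    anns.append(GoldAnnotation(note_id, feature_id))
                    continue
                if rng.random() < cfg.p_negation_variant:
                    surface = negation
                elif rng.random() < cfg.p_paraphrase:
                    surface = paraphrases[int(rng.integers(len(paraphrases)))]
                else:
                    surface = canonical
                if rng.random() < cfg.p_typo:
                    surface = _single_edit(surface, rng)
                if rng.random() < 0.3:
                    filler = _FILLERS[int(rng.integers(len(_FILLERS)))]
                    parts.append(" " + filler + ".")
                    offset += len(filler) + 2
                start = offset + 1  # leading space
                parts.append(" " + surface + ".")
                offset += len(surface) + 2
                anns.append(
                    GoldAnnotation(
                        note_id,
                        feature_id,
                        texts=(surface,),
                        spans=(((start, start + len(surface)),),),
                    )
                )
            notes.append(PatientNote(note_id, case_id, "".join(parts)))
            gold.extend(anns)
    return notes, features, gold


def _confidence_probs(
    target: float, n_tokens: int
) -> tuple[float, ...]:
    """Constant token probabilities whose geometric mean equals ``target``."""
    target = float(min(1.0, max(1e-6, target)))
    return tuple([target] * max(1, n_tokens))


def mock_extract(
    notes: list[PatientNote],
    features: list[FeatureSpec],
    gold: list[GoldAnnotation],
    profile: MockProfile | None = None,
    epoch: int = 0,
    seed: int = 0,
) -> list[Extraction]:
    """Mock extractor outputs: one record per (note, case feature).

    Present gold features are emitted with probability
    ``1 - miss_rate * decay^epoch`` (text possibly perturbed with
    probability ``paraphrase_noise``); absent ones are fabricated with
    probability ``hallucination_rate * decay^epoch``. Confidences are
    Beta-distributed, separately for correct and fabricated outputs.
    """
    profile = profile or MockProfile()
    rng = np.random.default_rng((seed, epoch, 77))
    decay = profile.epoch_decay**epoch
    eff_miss = profile.miss_rate * decay
    eff_hall = profile.hallucination_rate * decay

    feats_by_case: dict[str, list[FeatureSpec]] = {}
    for f in features:
        feats_by_case.setdefault(f.case_id, []).append(f)
    gold_by_key = {(g.note_id, g.feature_id): g for g in gold}

    out: list[Extraction] = []
    for note in notes:
        for f in feats_by_case.get(note.case_id, []):
            g = gold_by_key.get((note.note_id, f.feature_id))
            if g is not None and g.present:
                if rng.random() < eff_miss:
                    out.append(Extraction(note.note_id, f.feature_id, ""))
                    continue
                text = g.texts[0]
                if rng.random() < profile.paraphrase_noise:
                    text = _single_edit(text, rng)
                target = rng.beta(*profile.conf_correct)
                out.append(
                    Extraction(
                        note.note_id,
                        f.feature_id,
                        text,
                        _confidence_probs(target, len(tokenize(text))),
                    )
                )
            else:
                if rng.random() < eff_hall:
                    text = _FABRICATIONS[int(rng.integers(len(_FABRICATIONS)))]
                    target = rng.beta(*profile.conf_incorrect)
                    out.append(
                        Extraction(
                            note.note_id,
                            f.feature_id,
                            text,
                            _confidence_probs(target, len(tokenize(text))),
                        )
                    )
                else:
                    out.append(Extraction(note.note_id, f.feature_id, ""))
    return out


def epoch_series(
    notes: list[PatientNote],
    features: list[FeatureSpec],
    gold: list[GoldAnnotation],
    profile: MockProfile | None = None,
    n_epochs: int = 5,
    seed: int = 0,
) -> list[list[Extraction]]:
    """Extraction sets for epochs 0..n-1 with decaying effective error rates."""
    return [
        mock_extract(notes, features, gold, profile, epoch=e, seed=seed)
        for e in range(n_epochs)
    ]


class MockGenerator:
    """:class:`~notegate.objective.GeneratorContract` over the mock extractor.

    Precomputes one extraction set per epoch; :meth:`set_epoch` switches
    the active epoch before each :func:`~notegate.objective.run_epoch`
    call. Deterministic per seed.
    """

    def __init__(
        self,
        notes: list[PatientNote],
        features: list[FeatureSpec],
        gold: list[GoldAnnotation],
        profile: MockProfile | None = None,
        seed: int = 0,
    ):
        self._notes = notes
        self._features = features
        self._gold = gold
        self._profile = profile or MockProfile()
        self._seed = seed
        self._epoch = 0
        self._cache: dict[int, dict[tuple[str, str], Extraction]] = {}

    def set_epoch(self, epoch: int) -> None:
        self._epoch = epoch

    def _records(self, epoch: int) -> dict[tuple[str, str], Extraction]:
        if epoch not in self._cache:
            recs = mock_extract(
                self._notes, self._features, self._gold, self._profile, epoch, self._seed
            )
            self._cache[epoch] = {(r.note_id, r.feature_id): r for r in recs}
        return self._cache[epoch]

    def __call__(
        self, note: PatientNote, features: list[FeatureSpec]
    ) -> list[tuple[str, list[float]]]:
        recs = self._records(self._epoch)
        out = []
        for f in features:
            r = recs[(note.note_id, f.feature_id)]
            out.append((r.text, list(r.token_probs)))
        return out
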