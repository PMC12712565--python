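"""The confidence-regularized training objective.

The total training loss combines a base language-modeling cross-entropy
with two auxiliary penalties derived from bidirectional chrF matching:

    total = ce + 0.2 * hallucination_penalty + 0.5 * missing_penalty

The hallucination penalty fires only for *overconfident incorrect*
predictions: with penalty base ``b = hallucination_base(best F1)`` and
feature confidence ``c`` above the dynamic threshold ``tau``, the
per-feature term is ``b * (c + alpha * (c - tau)^2)`` with ``alpha = 2``
sharpening sensitivity to overconfidence. When both penalties are zero the
step carries no penalty gradient — the contract mirrors "no penalty, no
backpropagation" for differentiable generators; the reference mock path
merely asserts the flag.

Missing features weigh more (0.5) than hallucinations (0.2): the
first-phase extractor under-recalls, so omissions cost more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Protocol

import numpy as np

from notegate.confidence import (
    ConfidenceConfig,
    EpochState,
    dynamic_threshold,
    ema_feedback,
    feature_confidence,
)
from notegate.corpus import Extraction, FeatureSpec, GoldAnnotation, PatientNote
from notegate.matching import MatchReport, match_note, missing_penalty
from notegate.similarity import tokenize


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty weights and thresholds (defaults per the framework)."""

    alpha_penalty: float = 2.0
    w_hallucination: float = 0.2
    w_missing: float = 0.5
    miss_threshold: float = 0.5
    hall_reduced_cut: float = 0.3
    ngram_order: int = 3
    aggregation: str = "mean_all"
    penalty_form: Literal["proportional_plus_quadratic", "quadratic_only"] = (
        "proportional_plus_quadratic"
    )

    def __post_init__(self) -> None:
        for name in ("alpha_penalty", "w_hallucination", "w_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    """One training step's loss components; ``total`` is the exact linear form."""

    ce_loss: float
    hallucination_penalty: float
    missing_penalty: float
    total: float
    penalized_feature_count: int

    def __post_init__(self) -> None:
        for name in ("ce_loss", "hallucination_penalty", "missing_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def no_penalty_gradient(self) -> bool:
        """True when the step must not propagate any penalty gradient."""
        return self.hallucination_penalty == 0.0 and self.missing_penalty == 0.0


class GeneratorContract(Protocol):
    """Abstract extractor: one (text, token_probs) record per requested feature.

    An empty text means the generator reports the feature absent. A
    gradient-capable implementation must additionally skip the penalty
    backward pass whenever :attr:`LossBreakdown.no_penalty_gradient` holds.
    """

    def __call__(
        self, note: PatientNote, features: list[FeatureSpec]
    ) -> list[tuple[str, list[float]]]: ...


def overconfidence_penalty(
    base: float, confidence: float, tau: float, alpha_penalty: float = 2.0,
    form: str = "proportional_plus_quadratic",
) -> float:
    """Per-feature hallucination penalty, gated on overconfidence.

    Zero when ``confidence <= tau`` (not overconfident) or ``base == 0``
    (perfect match); otherwise ``base * (c + alpha * (c - tau)^2)``.
    The alternative ``quadratic_only`` form ``alpha * (c - tau)^2 * base``
    is available for sensitivity analysis.
    """
    if not (0.0 <= base <= 1.0):
        raise ValueError(f"base {base} outside [0, 1]")
    if not (0.0 <= confidence <= 1.0):
        raise ValueError(f"confidence {confidence} outside [0, 1]")
    if confidence <= tau or base == 0.0:
        return 0.0
    quad = alpha_penalty * (confidence - tau) ** 2
    if form == "proportional_plus_quadratic":
        return base * (confidence + quad)
    if form == "quadratic_only":
        return base * quad
    raise ValueError(f"unknown penalty form {form!r}")


def note_penalties(
    extractions: list[Extraction],
    gold: list[GoldAnnotation],
    tau: float,
    cfg: PenaltyConfig | None = None,
    conf_cfg: ConfidenceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, MatchReport]:
    """Hallucination and omission penalties for one note.

    The hallucination penalty is the mean over non-empty predictions of
    :func:`overconfidence_penalty` applied to each prediction's
    hallucination base and confidence; the omission penalty comes from
    backward matching. Confidences already stored on the extraction are
    used as-is; otherwise they are derived from ``token_probs`` through the
    confidence pipeline (noise only when ``rng`` is given).
    """
    cfg = cfg or PenaltyConfig()
    conf_cfg = conf_cfg or ConfidenceConfig()
    asserted = [e for e in extractions if e.asserted]
    note_id = extractions[0].note_id if extractions else ""
    report = match_note(note_id, asserted, gold, cfg.ngram_order, cfg.miss_threshold)

    per_feature = []
    for e, base in zip(asserted, report.hallucination_bases):
        if e.confidence is not None:
            c = e.confidence
        else:
            c = feature_confidence(e.token_probs, len(tokenize(e.text)), conf_cfg, rng)
        per_feature.append(
            overconfidence_penalty(base, c, tau, cfg.alpha_penalty, cfg.penalty_form)
        )
    hall = float(sum(per_feature) / len(per_feature)) if per_feature else 0.0
    miss = missing_penalty(list(report.backward), cfg.miss_threshold, cfg.aggregation)
    return hall, miss, report


def total_loss(
    ce: float, hall: float, miss: float, cfg: PenaltyConfig | None = None,
    penalized_feature_count: int = 0,
) -> LossBreakdown:
    """Combine components into the weighted total (exact linear identity)."""
    cfg = cfg or PenaltyConfig()
    if ce < 0 or hall < 0 or miss < 0:
        raise ValueError("loss components must be >= 0")
    return LossBreakdown(
        ce_loss=ce,
        hallucination_penalty=hall,
        missing_penalty=miss,
        total=ce + cfg.w_hallucination * hall + cfg.w_missing * miss,
        penalized_feature_count=penalized_feature_count,
    )


@dataclass(frozen=True)
class EpochResult:
    """One epoch's per-note losses, per-case penalty means, next state."""

    losses: dict[str, LossBreakdown]
    case_hallucination_mean: dict[str, float]
    case_missing_mean: dict[str, float]
    tau: float
    epoch_f1: float
    state: EpochState


def _binary_f1(
    extraction_by_key: dict[tuple[str, str], Extraction],
    gold_by_key: dict[tuple[str, str], GoldAnnotation],
    keys: list[tuple[str, str]],
) -> float:
    """Binary-overlap F1 on the training slice (cheap epoch feedback metric)."""
    from notegate.similarity import token_overlap_fraction

    tp = fp = fn = 0
    for key in keys:
        e = extraction_by_key.get(key)
        g = gold_by_key.get(key)
        pred = e is not None and e.asserted
        gold_present = g is not None and g.present
        if pred and gold_present:
            overlap = max(token_overlap_fraction(e.text, t).value for t in g.texts)
            if overlap >= 0.5:
                tp += 1
            else:
                fn += 1  # feature not recovered; the assertion scores absent
        elif pred:
            fp += 1
        elif gold_present:
            fn += 1
    if tp == 0:
        return 0.0 if (fp or fn) else 1.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def run_epoch(
    generator: GeneratorContract,
    notes: list[PatientNote],
    features: list[FeatureSpec],
    gold: list[GoldAnnotation],
    state: EpochState,
    cfg: PenaltyConfig | None = None,
    conf_cfg: ConfidenceConfig | None = None,
    ce_loss: float = 0.0,
) -> EpochResult:
    """Run one regularization epoch of the training loop against ``generator``.

    For every note the generator is asked for one record per case feature;
    penalties are computed with the epoch's dynamic threshold tau, and the
    state advances with the epoch's binary-overlap F1 and EMA-smoothed mean
    confidence. Deterministic given the config seed and a deterministic
    generator. ``ce_loss`` stands in for the base language-modeling loss,
    which the mock path does not compute.
    """
    if not notes:
        raise ValueError("corpus must contain at least one note")
    cfg = cfg or PenaltyConfig()
    conf_cfg = conf_cfg or ConfidenceConfig()
    tau = dynamic_threshold(state, conf_cfg)
    rng = np.random.default_rng((conf_cfg.seed, state.epoch_index))

    feats_by_case: dict[str, list[FeatureSpec]] = {}
    for f in features:
        feats_by_case.setdefault(f.case_id, []).append(f)
    gold_by_note: dict[str, list[GoldAnnotation]] = {}
    for g in gold:
        gold_by_note.setdefault(g.note_id, []).append(g)

    losses: dict[str, LossBreakdown] = {}
    case_hall: dict[str, list[float]] = {}
    case_miss: dict[str, list[float]] = {}
    all_ext: dict[tuple[str, str], Extraction] = {}
    gold_by_key = {(g.note_id, g.feature_id): g for g in gold}
    confidences: list[float] = []

    for note in notes:
        case_features = feats_by_case.get(note.case_id, [])
        records = generator(note, case_features)
        if len(records) != len(case_features):
            raise ValueError(
                f"generator returned {len(records)} records for note "
                f"{note.note_id!r} with {len(case_features)} features"
            )
        extractions = []
        for f, (text, probs) in zip(case_features, records):
            conf = None
            if text:
                conf = feature_confidence(probs, len(tokenize(text)), conf_cfg, rng)
                confidences.append(conf)
            e = Extraction(note.note_id, f.feature_id, text, tuple(probs), conf)
            extractions.append(e)
            all_ext[(note.note_id, f.feature_id)] = e
        hall, miss, report = note_penalties(
            extractions, gold_by_note.get(note.note_id, []), tau, cfg, conf_cfg
        )
        n_penalized = sum(1 for b in report.hallucination_bases if b > 0) + sum(
            1 for c in report.missing_contributions if c > 0
        )
        losses[note.note_id] = total_loss(ce_loss, hall, miss, cfg, n_penalized)
        case_hall.setdefault(note.case_id, []).append(hall)
        case_miss.setdefault(note.case_id, []).append(miss)

    keys = [(n.note_id, f.feature_id) for n in notes for f in feats_by_case.get(n.case_id, [])]
    epoch_f1 = _binary_f1(all_ext, gold_by_key, keys)
    mean_conf = float(np.mean(confidences)) if confidences else 0.0
    smoothed = ema_feedback(state.smoothed_confidence, mean_conf, conf_cfg.alpha_feedback)
    return EpochResult(
        losses=losses,
        case_hallucination_mean={c: float(np.mean(v)) for c, v in case_hall.items()},
        case_missing_mean={c: float(np.mean(v)) for c, v in case_miss.items()},
        tau=tau,
        epoch_f1=epoch_f1,
        state=state.advance(f1=epoch_f1, smoothed_confidence=smoothed),
    )
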