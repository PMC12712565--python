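"""Bidirectional chrF matching between predictions and gold features.

Hallucination is measured by *forward* matching: each non-empty prediction
takes its best character n-gram F1 against all gold phrasings; a best F1
above 0.3 earns a reduced penalty base of ``0.7 * (1 - F1)``, otherwise
the full ``1 - F1``. Omissions are measured by *backward* matching: each
gold feature takes its best F1 against all predictions, and those matched
below 0.5 count as missing. Per-feature argmax is intentional — no
bipartite assignment — so one strong prediction may cover several gold
features and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from notegate.corpus import Extraction, GoldAnnotation
from notegate.similarity import chrf_f1

Aggregation = Literal["mean_all", "mean_missing", "sum"]


@dataclass(frozen=True)
class DirectionalMatch:
    """Best-partner chrF match for one prediction (forward) or gold (backward)."""

    source_id: str
    best_f1: float
    best_partner_id: str | None
    direction: Literal["forward", "backward"]

    def __post_init__(self) -> None:
        if not (0.0 <= self.best_f1 <= 1.0):
            raise ValueError(f"best_f1 {self.best_f1} outside [0, 1]")
        if self.best_partner_id is None and self.best_f1 != 0.0:
            raise ValueError("missing partner only allowed with best_f1 = 0")


@dataclass(frozen=True)
class MatchReport:
    """Bidirectional match lists and derived penalty bases for one note."""

    note_id: str
    forward: tuple[DirectionalMatch, ...] = ()
    backward: tuple[DirectionalMatch, ...] = ()
    hallucination_bases: tuple[float, ...] = ()
    missing_contributions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.hallucination_bases) != len(self.forward):
            raise ValueError("one hallucination base per forward match required")
        if len(self.missing_contributions) != len(self.backward):
            raise ValueError("one missing contribution per backward match required")
        for v in self.hallucination_bases + self.missing_contributions:
            if v < 0:
                raise ValueError("penalty values must be >= 0")


def _gold_texts(gold: list[GoldAnnotation]) -> list[tuple[str, str]]:
    """(feature_id, phrasing) pairs over all alternatives of present golds."""
    out = []
    for g in gold:
        for text in g.texts:
            out.append((g.feature_id, text))
    return out


def _best_match(
    source_id: str,
    source_text: str,
    partners: list[tuple[str, str]],
    n: int,
    direction: Literal["forward", "backward"],
) -> DirectionalMatch:
    best_f1, best_id = 0.0, None
    for partner_id, partner_text in partners:
        f1 = chrf_f1(source_text, partner_text, n).value
        if f1 > best_f1:
            best_f1, best_id = f1, partner_id
    if best_id is None and partners:
        # all-zero similarities: record the fact with no partner
        best_id = None
    return DirectionalMatch(source_id, best_f1, best_id, direction)


def forward_match(
    predictions: list[Extraction], gold: list[GoldAnnotation], n: int = 3
) -> list[DirectionalMatch]:
    """Best gold partner for each non-empty prediction (hallucination side).

    Gold alternatives all participate; the best-scoring phrasing wins.
    With no gold phrasings every prediction scores 0.
    """
    partners = _gold_texts(gold)
    return [
        _best_match(p.feature_id, p.text, partners, n, "forward")
        for p in predictions
        if p.asserted
    ]


def backward_match(
    gold: list[GoldAnnotation], predictions: list[Extraction], n: int = 3
) -> list[DirectionalMatch]:
    """Best prediction partner for each present gold feature (omission side).

    Each present gold feature scores its best alternative against the best
    prediction; with no non-empty predictions every gold scores 0.
    """
    pred_partners = [(p.feature_id, p.text) for p in predictions if p.asserted]
    matches = []
    for g in gold:
        if not g.present:
            continue
        best = DirectionalMatch(g.feature_id, 0.0, None, "backward")
        for text in g.texts:
            m = _best_match(g.feature_id, text, pred_partners, n, "backward")
            if m.best_f1 >= best.best_f1:
                best = m
        matches.append(best)
    return matches


def hallucination_base(best_f1: float) -> float:
    """Penalty base for one prediction from its best forward F1.

    ``0.7 * (1 - F1)`` when F1 > 0.3 (partial credit), else the full
    ``1 - F1``. The boundary F1 = 0.3 takes the full branch.
    """
    if not (0.0 <= best_f1 <= 1.0):
        raise ValueError(f"best_f1 {best_f1} outside [0, 1]")
    if best_f1 > 0.3:
        return 0.7 * (1.0 - best_f1)
    return 1.0 - best_f1


def missing_contribution(best_f1: float, miss_threshold: float = 0.5) -> float:
    """Per-gold omission contribution: ``1 - F1`` when F1 < threshold, else 0."""
    if not (0.0 <= best_f1 <= 1.0):
        raise ValueError(f"best_f1 {best_f1} outside [0, 1]")
    return 1.0 - best_f1 if best_f1 < miss_threshold else 0.0


def missing_penalty(
    backward: list[DirectionalMatch],
    miss_threshold: float = 0.5,
    aggregation: Aggregation = "mean_all",
) -> float:
    """Aggregate the per-gold omission contributions into one note penalty.

    ``mean_all`` (default) averages over *all* present gold features so the
    penalty scales with the fraction missed; ``mean_missing`` averages over
    the missed ones only; ``sum`` adds them up. Zero when no gold features.
    """
    if not backward:
        return 0.0
    contributions = [missing_contribution(m.best_f1, miss_threshold) for m in backward]
    if aggregation == "mean_all":
        return float(sum(contributions) / len(contributions))
    if aggregation == "mean_missing":
        missed = [c for c in contributions if c > 0]
        return float(sum(missed) / len(missed)) if missed else 0.0
    if aggregation == "sum":
        return float(sum(contributions))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def match_note(
    note_id: str,
    predictions: list[Extraction],
    gold: list[GoldAnnotation],
    n: int = 3,
    miss_threshold: float = 0.5,
) -> MatchReport:
    """Full bidirectional match report for one note."""
    fwd = forward_match(predictions, gold, n)
    bwd = backward_match(gold, predictions, n)
    return MatchReport(
        note_id=note_id,
        forward=tuple(fwd),
        backward=tuple(bwd),
        hallucination_bases=tuple(hallucination_base(m.best_f1) for m in fwd),
        missing_contributions=tuple(
            missing_contribution(m.best_f1, miss_threshold) for m in bwd
        ),
    )
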