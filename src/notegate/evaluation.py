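"""Evaluation harness: presence scoring, P/R/F1, calibration, error ledger.

Two presence pipelines, never mixed:

* **binary overlap** — a feature counts as present when at least half of
  the gold phrase's tokens appear in the (gate-validated) prediction;
* **semantic** — present when embedding cosine between the extracted text
  and the rubric description is >= 0.5, with 0.5–0.7 flagged borderline
  for manual review.

Calibration uses *continuous* feature-level chrF scores against predicted
confidences (ECE over the four bins 0.6–0.7, 0.7–0.8, 0.8–0.9, 0.9–1.0
plus an optional underflow bin, and the Brier mean squared gap). The error
ledger counts hallucinations (false positives) and omissions (false
negatives) per model variant with half-up one-decimal rates and percent
reductions, matching the reporting style of published comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from notegate.corpus import Extraction, FeatureSpec, GoldAnnotation
from notegate.similarity import Embedder, embed_cosine, token_overlap_fraction

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (0.6, 0.7, 0.8, 0.9, 1.0)


def round1(x: float) -> float:
    """Half-up rounding to one decimal, as printed in reports."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PresenceDecision:
    """Present/absent call for one (note, feature) pair in one mode."""

    note_id: str
    feature_id: str
    present_pred: bool
    present_gold: bool
    mode: str  # binary_overlap | semantic
    similarity: float | None = None
    borderline: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("binary_overlap", "semantic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.borderline:
            if self.mode != "semantic" or self.similarity is None:
                raise ValueError("borderline requires semantic mode with similarity")
            if not (0.5 <= self.similarity <= 0.7):
                raise ValueError("borderline flag requires similarity in [0.5, 0.7]")

    @property
    def correct(self) -> bool:
        return self.present_pred == self.present_gold


@dataclass(frozen=True)
class CalibrationBin:
    """One reliability-diagram bin.

    ``gap`` is performance minus confidence (negative = overconfident);
    ``gap_to_optimum`` is mean score minus 1, the bin's distance below
    perfect performance.
    """

    lower: float
    upper: float
    count: int
    mean_confidence: float | None
    mean_score: float | None

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("bin lower must be < upper")
        if self.count < 0:
            raise ValueError("bin count must be >= 0")

    @property
    def gap(self) -> float | None:
        if self.count == 0:
            return None
        return self.mean_score - self.mean_confidence

    @property
    def gap_to_optimum(self) -> float | None:
        if self.count == 0:
            return None
        return self.mean_score - 1.0


def _is_asserted(extraction: Extraction | None) -> bool:
    """A prediction counts only when non-empty and not gate-rejected."""
    if extraction is None or not extraction.asserted:
        return False
    if extraction.gate is not None and not extraction.gate.validated:
        return False
    return True


def presence_binary_overlap(
    extraction: Extraction | None, gold: GoldAnnotation | None
) -> PresenceDecision:
    """Binary-overlap presence call: >= 50% of gold tokens recovered.

    With no gold phrase, any asserted (gate-validated) prediction counts as
    a false positive.
    """
    note_id = extraction.note_id if extraction else (gold.note_id if gold else "")
    feature_id = extraction.feature_id if extraction else (gold.feature_id if gold else "")
    asserted = _is_asserted(extraction)
    gold_present = gold is not None and gold.present
    similarity = None
    if asserted and gold_present:
        similarity = max(
            token_overlap_fraction(extraction.text, t).value for t in gold.texts
        )
        present_pred = similarity >= 0.5
    else:
        present_pred = asserted
    return PresenceDecision(
        note_id, feature_id, present_pred, gold_present, "binary_overlap", similarity
    )


def presence_semantic(
    extraction: Extraction | None,
    feature: FeatureSpec,
    embedder: Embedder,
    gold: GoldAnnotation | None = None,
) -> PresenceDecision:
    """Semantic presence call: embedding cosine vs the rubric description.

    Gate-rejected extractions are absent regardless of similarity; asserted
    ones are present iff cosine >= 0.5, borderline on [0.5, 0.7].
    """
    note_id = extraction.note_id if extraction else (gold.note_id if gold else "")
    asserted = _is_asserted(extraction)
    gold_present = gold is not None and gold.present
    similarity = None
    present_pred = False
    borderline = False
    if asserted:
        similarity = embed_cosine(extraction.text, feature.description, embedder).value
        present_pred = similarity >= 0.5
        borderline = present_pred and similarity <= 0.7
    return PresenceDecision(
        note_id,
        feature.feature_id,
        present_pred,
        gold_present,
        "semantic",
        similarity,
        borderline,
    )


def confusion_counts(decisions: list[PresenceDecision]) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) from presence decisions (single mode enforced)."""
    modes = {d.mode for d in decisions}
    if len(modes) > 1:
        raise ValueError(f"mixed decision modes {sorted(modes)}")
    tp = sum(d.present_pred and d.present_gold for d in decisions)
    fp = sum(d.present_pred and not d.present_gold for d in decisions)
    fn = sum(not d.present_pred and d.present_gold for d in decisions)
    tn = len(decisions) - tp - fp - fn
    return tp, fp, fn, tn


def prf(decisions: list[PresenceDecision]) -> tuple[float, float, float]:
    """Precision, recall and F1 from presence decisions.

    Conventions: with no predictions and existing gold, all three are 0;
    with neither predictions nor gold, all three are 1.
    """
    tp, fp, fn, _ = confusion_counts(decisions)
    if tp + fp == 0 and tp + fn == 0:
        return 1.0, 1.0, 1.0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


# ---------------------------------------------------------------------------
# calibration


def _bins(bin_edges: tuple[float, ...], underflow: bool) -> list[tuple[float, float]]:
    edges = list(bin_edges)
    bins = list(zip(edges[:-1], edges[1:]))
    if underflow and edges[0] > 0.0:
        bins.insert(0, (0.0, edges[0]))
    return bins


def _bin_index(c: float, bins: list[tuple[float, float]]) -> int | None:
    for i, (lo, hi) in enumerate(bins):
        # half-open bins, last bin closed at the top
        if lo <= c < hi or (i == len(bins) - 1 and c == hi):
            return i
    return None


def reliability_table(
    confidences: list[float],
    scores: list[float],
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    underflow: bool = True,
) -> list[CalibrationBin]:
    """Per-bin counts, mean confidence and mean score for the reliability diagram."""
    if len(confidences) != len(scores):
        raise ValueError("confidences and scores must have equal length")
    bins = _bins(bin_edges, underflow)
    members: list[list[tuple[float, float]]] = [[] for _ in bins]
    for c, s in zip(confidences, scores):
        idx = _bin_index(c, bins)
        if idx is not None:
            members[idx].append((c, s))
    table = []
    for (lo, hi), pairs in zip(bins, members):
        if pairs:
            mc = float(np.mean([c for c, _ in pairs]))
            ms = float(np.mean([s for _, s in pairs]))
            table.append(CalibrationBin(lo, hi, len(pairs), mc, ms))
        else:
            table.append(CalibrationBin(lo, hi, 0, None, None))
    return table


def ece(
    confidences: list[float],
    scores: list[float],
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    underflow: bool = True,
) -> float:
    """Expected calibration error: count-weighted mean absolute bin gap."""
    if len(confidences) != len(scores):
        raise ValueError("confidences and scores must have equal length")
    if len(confidences) == 0:
        warnings.warn("ece called with empty input; returning 0", stacklevel=2)
        return 0.0
    table = reliability_table(confidences, scores, bin_edges, underflow)
    total = sum(b.count for b in table)
    if total == 0:
        warnings.warn("no confidence fell into any bin; returning 0", stacklevel=2)
        return 0.0
    return float(
        sum(b.count / total * abs(b.mean_confidence - b.mean_score) for b in table if b.count)
    )


def brier(confidences: list[float], scores: list[float]) -> float:
    """Mean squared gap between confidence and (continuous) score."""
    if len(confidences) != len(scores):
        raise ValueError("confidences and scores must have equal length")
    if len(confidences) == 0:
        warnings.warn("brier called with empty input; returning 0", stacklevel=2)
        return 0.0
    c = np.asarray(confidences, dtype=float)
    s = np.asarray(scores, dtype=float)
    return float(np.mean((c - s) ** 2))


# ---------------------------------------------------------------------------
# error accounting


@dataclass(frozen=True)
class VariantErrors:
    """Error counts for one model variant on one corpus."""

    variant: str
    hallucinated_count: int
    missing_count: int
    total_features: int

    @property
    def hallucination_rate(self) -> float:
        """Percent of features hallucinated, half-up to one decimal."""
        return round1(100.0 * self.hallucinated_count / self.total_features)

    @property
    def miss_rate(self) -> float:
        return round1(100.0 * self.missing_count / self.total_features)


@dataclass(frozen=True)
class ErrorLedger:
    """Hallucination/omission accounting across model variants."""

    variants: tuple[VariantErrors, ...]

    def __getitem__(self, variant: str) -> VariantErrors:
        for v in self.variants:
            if v.variant == variant:
                return v
        raise KeyError(variant)

    @staticmethod
    def reduction(baseline_count: int, final_count: int) -> float | None:
        """Percent reduction ``100 * (b - f) / b``, half-up to one decimal.

        Undefined (None) when the baseline count is zero.
        """
        if baseline_count == 0:
            return None
        return round1(100.0 * (baseline_count - final_count) / baseline_count)

    def hallucination_reduction(self, baseline: str, final: str) -> float | None:
        return self.reduction(
            self[baseline].hallucinated_count, self[final].hallucinated_count
        )

    def missing_reduction(self, baseline: str, final: str) -> float | None:
        return self.reduction(self[baseline].missing_count, self[final].missing_count)


def error_ledger(
    decisions_by_variant: dict[str, list[PresenceDecision]],
    extractions_by_variant: dict[str, list[Extraction]] | None = None,
    count_rejected_as_hallucination: bool = True,
) -> ErrorLedger:
    """Count hallucinations and omissions per model variant.

    Hallucinations are presence false positives plus — by default — any
    asserted extraction the matching gate rejected (an extraction claiming
    a feature the note cannot support), when gate outcomes are supplied.
    Omissions are false negatives.
    """
    if not decisions_by_variant:
        raise ValueError("at least one model variant required")
    variants = []
    for name, decisions in decisions_by_variant.items():
        tp, fp, fn, tn = confusion_counts(decisions)
        hallucinated = fp
        if count_rejected_as_hallucination and extractions_by_variant:
            hallucinated += sum(
                1
                for e in extractions_by_variant.get(name, [])
                if e.asserted and e.gate is not None and not e.gate.validated
            )
        variants.append(VariantErrors(name, hallucinated, fn, len(decisions)))
    return ErrorLedger(tuple(variants))


def per_feature_error_rates(
    decisions: list[PresenceDecision],
) -> dict[str, tuple[float, float]]:
    """Per-feature (hallucination rate, miss rate) in percent.

    Hallucination rate is the false-positive share FP/(TP+FP) and miss
    rate the false-negative share FN/(TP+FN), per feature; 0 when the
    denominator is empty.
    """
    by_feature: dict[str, list[PresenceDecision]] = {}
    for d in decisions:
        by_feature.setdefault(d.feature_id, []).append(d)
    rates = {}
    for fid, ds in by_feature.items():
        tp, fp, fn, _ = confusion_counts(ds)
        hall = round1(100.0 * fp / (tp + fp)) if tp + fp else 0.0
        miss = round1(100.0 * fn / (tp + fn)) if tp + fn else 0.0
        rates[fid] = (hall, miss)
    return rates


# ---------------------------------------------------------------------------
# paired significance tests


def _f1_of(decisions: list[PresenceDecision]) -> float:
    return prf(decisions)[2]


def mcnemar_p(b: int, c: int, exact_cutoff: int = 25) -> float:
    """McNemar test p-value from the discordant-pair counts (b, c).

    Exact two-sided binomial when b + c < ``exact_cutoff``; chi-square with
    continuity correction otherwise. No discordant pairs -> p = 1.
    """
    n = b + c
    if n == 0:
        return 1.0
    if n < exact_cutoff:
        k = min(b, c)
        return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))
    stat = (abs(b - c) - 1.0) ** 2 / n
    return float(stats.chi2.sf(stat, df=1))


def paired_comparison(
    decisions_a: list[PresenceDecision],
    decisions_b: list[PresenceDecision],
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float], float]:
    """Compare two models on aligned decisions.

    Returns ``(f1_b - f1_a, percentile 95% CI from note-level bootstrap,
    McNemar p on the per-feature correctness discordance table)``.
    Deterministic under ``seed``. Raises on misaligned (note, feature)
    keys.
    """
    key = lambda d: (d.note_id, d.feature_id)
    a_by = {key(d): d for d in decisions_a}
    b_by = {key(d): d for d in decisions_b}
    if set(a_by) != set(b_by):
        raise ValueError("decision sets are not aligned on (note, feature) keys")

    keys = sorted(a_by)
    diff = _f1_of(decisions_b) - _f1_of(decisions_a)

    b_count = sum(a_by[k].correct and not b_by[k].correct for k in keys)
    c_count = sum(not a_by[k].correct and b_by[k].correct for k in keys)
    p = mcnemar_p(b_count, c_count)

    notes = sorted({k[0] for k in keys})
    by_note_a: dict[str, list[PresenceDecision]] = {n: [] for n in notes}
    by_note_b: dict[str, list[PresenceDecision]] = {n: [] for n in notes}
    for k in keys:
        by_note_a[k[0]].append(a_by[k])
        by_note_b[k[0]].append(b_by[k])

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        sample = rng.choice(len(notes), size=len(notes), replace=True)
        da = [d for j in sample for d in by_note_a[notes[j]]]
        db = [d for j in sample for d in by_note_b[notes[j]]]
        diffs[i] = _f1_of(db) - _f1_of(da)
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    return diff, ci, p


def review_queue(decisions: list[PresenceDecision]) -> list[PresenceDecision]:
    """Items flagged for manual review: borderline matches then misses.

    Borderline semantic matches come first, ordered by ascending
    similarity; false negatives are appended (ascending similarity, items
    without a similarity last).
    """
    for d in decisions:
        if d.mode != "semantic":
            raise ValueError("review_queue requires semantic-mode decisions")
    borderline = sorted(
        (d for d in decisions if d.borderline), key=lambda d: d.similarity
    )
    misses = sorted(
        (d for d in decisions if d.present_gold and not d.present_pred),
        key=lambda d: (d.similarity is None, d.similarity or 0.0),
    )
    return borderline + misses
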