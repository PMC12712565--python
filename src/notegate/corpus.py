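"""Data model and readers/writers for notes, rubrics, gold spans and extractions.

Conventions: character offsets are 0-based half-open into the *original*
note text; a gold location string is ``"start end"`` with discontinuous
segments joined by ``";"``; one gold annotation may carry several
alternative phrasings (one location string each). Absent features are
explicit records with an empty alternative list / empty extraction text,
never missing rows, so omission accounting stays unambiguous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from notegate.similarity import normalize

logger = logging.getLogger(__name__)

Span = tuple[int, int]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class PatientNote:
    """One note's free text with identifiers and case linkage."""

    note_id: str
    case_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"note {self.note_id!r} has empty text")


@dataclass(frozen=True)
class FeatureSpec:
    """One rubric feature a note must be searched for."""

    feature_id: str
    case_id: str
    description: str

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError(f"feature {self.feature_id!r} has empty description")


@dataclass(frozen=True)
class GoldAnnotation:
    """Expert annotation of one feature in one note.

    ``texts[i]`` is the i-th alternative phrasing; ``spans[i]`` its list of
    (start, end) segments into the note. An empty ``texts`` means the
    feature is absent from the note (gold = None). Invariant: each
    alternative's segments, sliced from the note and joined with spaces,
    equal the stored text after normalization.
    """

    note_id: str
    feature_id: str
    texts: tuple[str, ...] = ()
    spans: tuple[tuple[Span, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.texts) != len(self.spans):
            raise ValueError("texts and spans must have one entry per alternative")
        for segs in self.spans:
            for start, end in segs:
                if start < 0 or end < start:
                    raise ValueError(f"malformed span ({start}, {end})")

    @property
    def present(self) -> bool:
        return len(self.texts) > 0

    def validate_against(self, note: PatientNote) -> None:
        """Check the span-reconstruction invariant against ``note``."""
        if note.note_id != self.note_id:
            raise ValueError("annotation/note id mismatch")
        for text, segs in zip(self.texts, self.spans):
            for start, end in segs:
                if end > len(note.text):
                    raise ValueError(
                        f"span ({start}, {end}) outside note {note.note_id!r} "
                        f"of length {len(note.text)}"
                    )
            rebuilt = " ".join(note.text[s:e] for s, e in segs)
            if normalize(rebuilt).normalized != normalize(text).normalized:
                raise ValueError(
                    f"span text {rebuilt!r} does not reconstruct {text!r} "
                    f"for feature {self.feature_id!r} in note {note.note_id!r}"
                )


@dataclass(frozen=True)
class GateDecision:
    """Outcome of the inference matching gate for one extraction.

    ``status`` is ``"validated"`` or ``"rejected"``; ``method`` names the
    gate step that fired (``exact``/``levenshtein``/``sentence_tfidf``/
    ``windowed``) or ``none`` for rejections. Validated decisions carry the
    evidence span(s) into the original note text.
    """

    status: str
    method: str
    span: tuple[Span, ...] = ()
    matched_text: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("validated", "rejected"):
            raise ValueError(f"unknown gate status {self.status!r}")
        if self.status == "validated" and not self.span:
            raise ValueError("validated decision requires a non-empty span")
        if self.status == "rejected" and self.span:
            raise ValueError("rejected decision must not carry a span")

    @property
    def validated(self) -> bool:
        return self.status == "validated"


@dataclass(frozen=True)
class Extraction:
    """One extractor output for a (note, feature) pair.

    Empty ``text`` means the extractor reports the feature absent.
    ``token_probs`` are per-token generation probabilities in (0, 1];
    ``confidence`` is the aggregated feature-level confidence once the
    confidence pipeline has run; ``gate`` the inference gate decision.
    """

    note_id: str
    feature_id: str
    text: str
    token_probs: tuple[float, ...] = ()
    confidence: float | None = None
    gate: GateDecision | None = None

    def __post_init__(self) -> None:
        for p in self.token_probs:
            if not (0.0 < p <= 1.0):
                raise ValueError(f"token probability {p} outside (0, 1]")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def asserted(self) -> bool:
        """Whether the extractor asserts the feature (non-empty text)."""
        return bool(self.text)


# ---------------------------------------------------------------------------
# location-string parsing / formatting


def parse_location(location: str) -> tuple[Span, ...]:
    """Parse ``"start end[;start end]"`` into (start, end) segments.

    Raises ValueError on malformed input (wrong arity, non-integers,
    start > end, negative offsets).
    """
    segments: list[Span] = []
    for part in location.split(";"):
        fields = part.split()
        if len(fields) != 2:
            raise ValueError(f"malformed location segment {part!r}")
        start, end = int(fields[0]), int(fields[1])
        if start < 0 or end < start:
            raise ValueError(f"malformed interval ({start}, {end}) in {location!r}")
        segments.append((start, end))
    if not segments:
        raise ValueError(f"empty location string {location!r}")
    return tuple(segments)


def format_location(segments: tuple[Span, ...]) -> str:
    return ";".join(f"{s} {e}" for s, e in segments)


# ---------------------------------------------------------------------------
# CSV corpus I/O


def _require_columns(df: pd.DataFrame, columns: list[str], path: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_corpus_csv(
    notes_path: str | Path,
    features_path: str | Path,
    annotations_path: str | Path,
) -> tuple[list[PatientNote], list[FeatureSpec], list[GoldAnnotation]]:
    """Read the three corpus tables and validate span/text agreement.

    Annotation rows whose locations are malformed or fail span
    reconstruction are skipped with a logged count rather than aborting the
    read; missing columns raise :class:`SchemaError` immediately.
    """
    notes_df = pd.read_csv(notes_path, dtype=str).fillna("")
    _require_columns(notes_df, ["note_id", "case_id", "text"], str(notes_path))
    notes = [
        PatientNote(row.note_id, row.case_id, row.text)
        for row in notes_df.itertuples(index=False)
    ]
    by_id = {n.note_id: n for n in notes}
    if len(by_id) != len(notes):
        raise ValueError("duplicate note_id in notes table")

    feats_df = pd.read_csv(features_path, dtype=str).fillna("")
    _require_columns(feats_df, ["feature_id", "case_id", "description"], str(features_path))
    features = [
        FeatureSpec(row.feature_id, row.case_id, row.description)
        for row in feats_df.itertuples(index=False)
    ]

    ann_df = pd.read_csv(annotations_path, dtype=str).fillna("")
    _require_columns(
        ann_df, ["note_id", "feature_id", "texts", "locations"], str(annotations_path)
    )
    gold: list[GoldAnnotation] = []
    skipped = 0
    for row in ann_df.itertuples(index=False):
        try:
            texts = tuple(json.loads(row.texts) if row.texts else [])
            locations = tuple(json.loads(row.locations) if row.locations else [])
            spans = tuple(parse_location(loc) for loc in locations)
            ann = GoldAnnotation(row.note_id, row.feature_id, texts, spans)
            note = by_id.get(row.note_id)
            if note is None:
                raise ValueError(f"annotation references unknown note {row.note_id!r}")
            ann.validate_against(note)
        except (ValueError, json.JSONDecodeError) as exc:
            logger.warning(
                "skipping annotation (%s, %s): %s", row.note_id, row.feature_id, exc
            )
            skipped += 1
            continue
        gold.append(ann)
    if skipped:
        logger.warning("skipped %d malformed annotation rows", skipped)
    return notes, features, gold


def write_corpus_csv(
    notes: list[PatientNote],
    features: list[FeatureSpec],
    gold: list[GoldAnnotation],
    notes_path: str | Path,
    features_path: str | Path,
    annotations_path: str | Path,
) -> None:
    """Write the three corpus tables in the schema :func:`read_corpus_csv` reads."""
    pd.DataFrame(
        [(n.note_id, n.case_id, n.text) for n in notes],
        columns=["note_id", "case_id", "text"],
    ).to_csv(notes_path, index=False)
    pd.DataFrame(
        [(f.feature_id, f.case_id, f.description) for f in features],
        columns=["feature_id", "case_id", "description"],
    ).to_csv(features_path, index=False)
    pd.DataFrame(
        [
            (
                g.note_id,
                g.feature_id,
                json.dumps(list(g.texts)),
                json.dumps([format_location(segs) for segs in g.spans]),
            )
            for g in gold
        ],
        columns=["note_id", "feature_id", "texts", "locations"],
    ).to_csv(annotations_path, index=False)


# ---------------------------------------------------------------------------
# extraction JSONL I/O


def _extraction_to_dict(rec: Extraction) -> dict[str, Any]:
    d: dict[str, Any] = {
        "note_id": rec.note_id,
        "feature_id": rec.feature_id,
        "text": rec.text,
        "token_probs": list(rec.token_probs),
    }
    if rec.confidence is not None:
        d["confidence"] = rec.confidence
    if rec.gate is not None:
        d["gate"] = {
            "status": rec.gate.status,
            "method": rec.gate.method,
            "span": format_location(rec.gate.span) if rec.gate.span else "",
            "matched_text": rec.gate.matched_text,
        }
    return d


def _extraction_from_dict(d: dict[str, Any]) -> Extraction:
    gate = None
    if "gate" in d:
        g = d["gate"]
        gate = GateDecision(
            status=g["status"],
            method=g["method"],
            span=parse_location(g["span"]) if g.get("span") else (),
            matched_text=g.get("matched_text", ""),
        )
    return Extraction(
        note_id=d["note_id"],
        feature_id=d["feature_id"],
        text=d["text"],
        token_probs=tuple(d.get("token_probs", ())),
        confidence=d.get("confidence"),
        gate=gate,
    )


def read_extractions_jsonl(path: str | Path) -> list[Extraction]:
    """Read extraction records, one JSON object per line.

    Malformed JSON or contract violations raise with the 1-based line
    number in the message.
    """
    records: list[Extraction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(_extraction_from_dict(json.loads(line)))
            except (json.JSONDecodeError, ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_extractions_jsonl(records: list[Extraction], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(_extraction_to_dict(rec)) + "\n")
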