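"""Inference-time matching gate: validate extractions against the note text.

Three steps, tried in order, first success wins:

1. **exact** — whitespace-flexible, case-insensitive substring search;
   failing that, the best token-aligned window by normalized Levenshtein
   similarity (catches misspellings);
2. **sentence** — best note sentence by TF-IDF cosine (document
   frequencies from the note's own sentences), with the extraction's
   tokens aligned to that sentence's matching token runs (possibly
   discontinuous evidence span);
3. **windowed** — sliding token window scored by the fraction of
   extraction tokens it covers (catches features scattered across a
   region).

Only text-supported extractions pass; everything else is rejected, which
is the inference-time hallucination filter. All offsets index the
original note text. Ties break leftmost-then-shortest. Thresholds are
package defaults, not quantities inherited from any reference system.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from notegate.corpus import Extraction, GateDecision, PatientNote, Span
from notegate.similarity import (
    levenshtein_norm,
    normalize,
    tfidf_cosine,
    token_overlap_fraction,
    tokenize,
)

_SENTENCE_SPLIT = re.compile(r"[.;!?\n]+")
_TOKEN = re.compile(r"\S+")


@dataclass(frozen=True)
class GateConfig:
    """Thresholds of the three gate steps."""

    lev_norm_min: float = 0.85
    tfidf_min: float = 0.5
    window_overlap_min: float = 0.5
    window_slack: int = 2

    def __post_init__(self) -> None:
        for name in ("lev_norm_min", "tfidf_min", "window_overlap_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.window_slack < 0:
            raise ValueError("window_slack must be >= 0")


def _note_tokens(note_text: str) -> list[tuple[int, int, str]]:
    """(start, end, raw token) for every whitespace-delimited token."""
    return [(m.start(), m.end(), m.group()) for m in _TOKEN.finditer(note_text)]


def _stripped_tokens(note_text: str) -> list[tuple[int, int, str]]:
    """Token offsets with surrounding punctuation excluded (empties dropped)."""
    import string

    out = []
    for start, end, raw in _note_tokens(note_text):
        lead = len(raw) - len(raw.lstrip(string.punctuation))
        core = raw.strip(string.punctuation)
        if core:
            out.append((start + lead, start + lead + len(core), core))
    return out


def _sentences(note_text: str) -> list[tuple[int, int, str]]:
    """(start, end, text) sentence segments split on . ; ! ? and newlines."""
    out = []
    pos = 0
    for m in _SENTENCE_SPLIT.finditer(note_text):
        seg = note_text[pos : m.start()]
        if seg.strip():
            lead = len(seg) - len(seg.lstrip())
            trail = len(seg) - len(seg.rstrip())
            out.append((pos + lead, m.start() - trail, seg.strip()))
        pos = m.end()
    seg = note_text[pos:]
    if seg.strip():
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        out.append((pos + lead, len(note_text) - trail, seg.strip()))
    return out


def gate_exact(
    extraction_text: str, note: PatientNote, cfg: GateConfig | None = None
) -> GateDecision | None:
    """Step 1: flexible substring search, then Levenshtein window match."""
    cfg = cfg or GateConfig()
    chunks = normalize(extraction_text).normalized.split(" ")
    if not chunks or chunks == [""]:
        return None
    pattern = r"\s+".join(re.escape(c) for c in chunks)
    m = re.search(pattern, note.text, flags=re.IGNORECASE)
    if m is not None:
        span: Span = (m.start(), m.end())
        return GateDecision(
            status="validated",
            method="exact",
            span=(span,),
            matched_text=note.text[span[0] : span[1]],
        )

    # Levenshtein fallback over token-aligned windows of size ~ the
    # extraction's token count (leftmost-then-shortest tie-break);
    # punctuation-stripped boundaries so a trailing period cannot mask a typo.
    tokens = _stripped_tokens(note.text)
    k = len(chunks)
    target = normalize(extraction_text).normalized
    best: tuple[float, int, int, Span] | None = None  # (-score, start, length, span)
    for size in range(max(1, k - 1), k + 2):
        for i in range(len(tokens) - size + 1):
            start, end = tokens[i][0], tokens[i + size - 1][1]
            window = normalize(note.text[start:end]).normalized
            score = levenshtein_norm(window, target).value
            if score < cfg.lev_norm_min:
                continue
            key = (-score, start, end - start, (start, end))
            if best is None or key < best:
                best = key
    if best is None:
        return None
    span = best[3]
    return GateDecision(
        status="validated",
        method="levenshtein",
        span=(span,),
        matched_text=note.text[span[0] : span[1]],
    )


def gate_sentence(
    extraction_text: str, note: PatientNote, cfg: GateConfig | None = None
) -> GateDecision | None:
    """Step 2: best sentence by TF-IDF cosine, token-run aligned evidence."""
    cfg = cfg or GateConfig()
    sentences = _sentences(note.text)
    if not sentences:
        return None
    corpus = [s[2] for s in sentences]
    best: tuple[float, int] | None = None  # (-score, index)
    for idx, (_, _, sent) in enumerate(sentences):
        score = tfidf_cosine(extraction_text, sent, corpus).value
        if score < cfg.tfidf_min:
            continue
        key = (-score, idx)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    sent_start, sent_end, _ = sentences[best[1]]

    # align extraction tokens to matching token runs inside the sentence
    ext_tokens = set(tokenize(extraction_text))
    runs: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for start, end, raw in _stripped_tokens(note.text[sent_start:sent_end]):
        tok = tokenize(raw)
        if tok and tok[0] in ext_tokens:
            current.append((sent_start + start, sent_start + end))
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    if not runs:
        return None
    spans = tuple((run[0][0], run[-1][1]) for run in runs)
    matched = " ".join(note.text[s:e] for s, e in spans)
    return GateDecision(
        status="validated", method="sentence_tfidf", span=spans, matched_text=matched
    )


def gate_windowed(
    extraction_text: str, note: PatientNote, cfg: GateConfig | None = None
) -> GateDecision | None:
    """Step 3: sliding token window maximizing extraction-token coverage."""
    cfg = cfg or GateConfig()
    ext_tokens = tokenize(extraction_text)
    if not ext_tokens:
        return None
    tokens = _stripped_tokens(note.text)
    size = min(len(ext_tokens) + cfg.window_slack, max(len(tokens), 1))
    ext_set = set(ext_tokens)
    best: tuple[float, int, int, tuple[Span, ...]] | None = None
    for i in range(max(1, len(tokens) - size + 1)):
        window = tokens[i : i + size]
        if not window:
            continue
        window_text = note.text[window[0][0] : window[-1][1]]
        score = token_overlap_fraction(window_text, extraction_text).value
        if score < cfg.window_overlap_min:
            continue
        matched = [
            (s, e) for s, e, raw in window if tokenize(raw) and tokenize(raw)[0] in ext_set
        ]
        if not matched:
            continue
        span = (matched[0][0], matched[-1][1])
        key = (-score, span[0], span[1] - span[0], (span,))
        if best is None or key < best:
            best = key
    if best is None:
        return None
    span = best[3]
    return GateDecision(
        status="validated",
        method="windowed",
        span=span,
        matched_text=note.text[span[0][0] : span[0][1]],
    )


_STEPS = {
    "exact": gate_exact,
    "sentence": gate_sentence,
    "windowed": gate_windowed,
}


def validate(
    extraction: Extraction | str,
    note: PatientNote,
    cfg: GateConfig | None = None,
    steps: tuple[str, ...] = ("exact", "sentence", "windowed"),
) -> GateDecision:
    """Run the gate steps in order; first success wins, else reject.

    Empty extraction text is rejected with method ``none``. Accepts either
    an :class:`Extraction` or a bare string.
    """
    cfg = cfg or GateConfig()
    text = extraction.text if isinstance(extraction, Extraction) else extraction
    if not text:
        return GateDecision(status="rejected", method="none")
    for step in steps:
        decision = _STEPS[step](text, note, cfg)
        if decision is not None:
            return decision
    return GateDecision(status="rejected", method="none")


def apply_gate(
    extractions: list[Extraction],
    notes: list[PatientNote],
    cfg: GateConfig | None = None,
) -> list[Extraction]:
    """Attach a gate decision to every extraction (returns new records)."""
    from dataclasses import replace

    by_id = {n.note_id: n for n in notes}
    out = []
    for e in extractions:
        note = by_id.get(e.note_id)
        if note is None:
            raise ValueError(f"extraction references unknown note {e.note_id!r}")
        out.append(replace(e, gate=validate(e, note, cfg)))
    return out
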