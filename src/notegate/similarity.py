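"""Text normalization and pairwise similarity primitives.

Everything downstream — bidirectional matching, the inference gate, the
evaluation harness — reduces to the handful of pure string similarities
defined here: a single-order character n-gram F1 (the chrF family with one
n and balanced precision/recall), Levenshtein distance, gold-relative token
overlap, TF-IDF cosine, and a pluggable embedding cosine.

All operations normalize their inputs (lowercase, collapse whitespace runs,
strip) and are deterministic.
"""

from __future__ import annotations

import logging
import math
import string
from collections import Counter
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import edlib
import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity

logger = logging.getLogger(__name__)

_METHODS = frozenset(
    {"chrf", "token_overlap", "tfidf_cosine", "embed_cosine", "levenshtein_norm"}
)

#: Callable mapping any string to a fixed-length real vector.
Embedder = Callable[[str], np.ndarray]


@dataclass(frozen=True)
class NormalizedText:
    """A string paired with its canonical normalized form.

    Normalization lowercases, collapses whitespace runs (spaces, tabs,
    newlines) to single spaces, and strips leading/trailing space. The
    operation is idempotent.
    """

    raw: str
    normalized: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "normalized", " ".join(self.raw.lower().split()))

    def __len__(self) -> int:
        return len(self.normalized)


@dataclass(frozen=True)
class NgramProfile:
    """Multiset of the character n-grams of a normalized string."""

    n: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n-gram order must be >= 1, got {self.n}")
        for gram in self.counts:
            if len(gram) != self.n:
                raise ValueError(f"gram {gram!r} has length != n={self.n}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SimilarityScore:
    """A similarity value in [0, 1] tagged with the method that produced it."""

    value: float
    method: str

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown similarity method {self.method!r}")
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"similarity value {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


def normalize(text: str) -> NormalizedText:
    """Normalize ``text`` (lowercase, collapse whitespace, strip)."""
    return NormalizedText(text)


def tokenize(text: str) -> list[str]:
    """Split normalized text on spaces, stripping surrounding punctuation.

    Empty tokens (e.g. bare punctuation) are dropped. No stop-word removal.
    """
    tokens = []
    for tok in normalize(text).normalized.split(" "):
        tok = tok.strip(string.punctuation)
        if tok:
            tokens.append(tok)
    return tokens


def char_ngrams(text: str | NormalizedText, n: int) -> NgramProfile:
    """Multiset of all contiguous length-``n`` substrings of normalized text.

    Spaces count as characters. Strings shorter than ``n`` yield an empty
    profile.
    """
    if n < 1:
        raise ValueError(f"n-gram order must be >= 1, got {n}")
    s = text.normalized if isinstance(text, NormalizedText) else normalize(text).normalized
    counts = Counter(s[i : i + n] for i in range(len(s) - n + 1))
    return NgramProfile(n=n, counts=dict(counts))


def chrf_f1(
    candidate: str,
    reference: str,
    n: int = 3,
    *,
    set_semantics: bool = False,
) -> SimilarityScore:
    """Single-order character n-gram F1 between two strings.

    Precision is the fraction of the candidate's n-grams found in the
    reference, recall the converse, both with clipped multiset counts
    (``set_semantics=True`` collapses counts to presence/absence), and
    F1 = 2PR/(P+R). Equal normalized strings score 1 even when shorter than
    ``n``; otherwise an empty profile on either side scores 0.
    """
    a = normalize(candidate).normalized
    b = normalize(reference).normalized
    if a == b:
        return SimilarityScore(1.0, "chrf")
    pa = char_ngrams(a, n).counts
    pb = char_ngrams(b, n).counts
    if set_semantics:
        pa = {g: 1 for g in pa}
        pb = {g: 1 for g in pb}
    tot_a = sum(pa.values())
    tot_b = sum(pb.values())
    if tot_a == 0 or tot_b == 0:
        return SimilarityScore(0.0, "chrf")
    inter = sum(min(c, pb.get(g, 0)) for g, c in pa.items())
    if inter == 0:
        return SimilarityScore(0.0, "chrf")
    p = inter / tot_a
    r = inter / tot_b
    return SimilarityScore(2 * p * r / (p + r), "chrf")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute) between raw strings."""
    if a == b:
        return 0
    return int(edlib.align(a, b, task="distance")["editDistance"])


def levenshtein_norm(a: str, b: str) -> SimilarityScore:
    """Length-normalized edit similarity: ``1 - dist / max(len a, len b)``.

    Two empty strings score 1; the score is 1 iff the strings are equal.
    """
    m = max(len(a), len(b))
    if m == 0:
        return SimilarityScore(1.0, "levenshtein_norm")
    return SimilarityScore(1.0 - levenshtein(a, b) / m, "levenshtein_norm")


def token_overlap_fraction(pred: str, gold: str) -> SimilarityScore:
    """Fraction of the gold phrase's tokens recovered by the prediction.

    Set semantics over :func:`tokenize` output; the denominator is the gold
    token set ("how much of the rubric wording did the prediction cover").
    Returns 0 when gold has no tokens.
    """
    gold_toks = set(tokenize(gold))
    if not gold_toks:
        return SimilarityScore(0.0, "token_overlap")
    pred_toks = set(tokenize(pred))
    return SimilarityScore(len(gold_toks & pred_toks) / len(gold_toks), "token_overlap")


def _tfidf_vectorizer(corpus: Sequence[str]) -> TfidfVectorizer:
    vec = TfidfVectorizer(
        tokenizer=tokenize,
        preprocessor=lambda s: s,
        token_pattern=None,
        lowercase=False,
        smooth_idf=True,
    )
    vec.fit(list(corpus))
    return vec


def tfidf_cosine(a: str, b: str, corpus: Sequence[str]) -> SimilarityScore:
    """Cosine similarity of TF-IDF vectors, document frequencies from ``corpus``.

    Uses smoothed IDF (document counts incremented by one). Tokens absent
    from the corpus vocabulary carry no weight. Either vector zero -> 0.
    """
    if len(corpus) == 0:
        raise ValueError("tfidf_cosine requires a non-empty corpus")
    try:
        vec = _tfidf_vectorizer(corpus)
    except ValueError:
        # corpus with no usable tokens at all -> empty vocabulary
        return SimilarityScore(0.0, "tfidf_cosine")
    m = vec.transform([a, b])
    if m[0].nnz == 0 or m[1].nnz == 0:
        return SimilarityScore(0.0, "tfidf_cosine")
    cos = float(cosine_similarity(m[0], m[1])[0, 0])
    return SimilarityScore(min(1.0, max(0.0, cos)), "tfidf_cosine")


def embed_cosine(a: str, b: str, embedder: Embedder) -> SimilarityScore:
    """Cosine similarity between ``embedder(a)`` and ``embedder(b)``, floored at 0.

    A zero embedding on either side yields 0 with a logged warning.
    """
    va = np.asarray(embedder(a), dtype=float)
    vb = np.asarray(embedder(b), dtype=float)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        logger.warning("zero-vector embedding for %r or %r; similarity set to 0", a, b)
        return SimilarityScore(0.0, "embed_cosine")
    cos = float(va @ vb / (na * nb))
    return SimilarityScore(min(1.0, max(0.0, cos)), "embed_cosine")


class BagOfWordsEmbedder:
    """Deterministic hashing bag-of-words embedder.

    Maps each token (via a stable MD5 hash) to one of ``dim`` buckets and
    counts occurrences; cosine between two embeddings then reflects token
    overlap. Serves as the default deterministic stand-in wherever the
    embedding contract is needed without a sentence-embedding model.
    """

    def __init__(self, dim: int = 512):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim

    def _bucket(self, token: str) -> int:
        import hashlib

        return int(hashlib.md5(token.encode("utf-8")).hexdigest(), 16) % self.dim

    def __call__(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        for tok in tokenize(text):
            v[self._bucket(tok)] += 1.0
        return v
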