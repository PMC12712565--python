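"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive code paths: nested loops, no shared helpers with the
package beyond trivial normalization, so agreement is meaningful.
"""

from __future__ import annotations

import string


def norm(text: str) -> str:
    return " ".join(text.lower().split())


def grams(text: str, n: int) -> list[str]:
    s = norm(text)
    return [s[i : i + n] for i in range(len(s) - n + 1)]


def chrf_oracle(candidate: str, reference: str, n: int) -> float:
    """Clipped-multiset n-gram F1 by direct enumeration."""
    if norm(candidate) == norm(reference):
        return 1.0
    ga, gb = grams(candidate, n), grams(reference, n)
    if not ga or not gb:
        return 0.0
    gb_pool = list(gb)
    inter = 0
    for g in ga:
        if g in gb_pool:
            gb_pool.remove(g)
            inter += 1
    p = inter / len(ga)
    r = inter / len(gb)
    return 2 * p * r / (p + r) if p + r else 0.0


def levenshtein_oracle(a: str, b: str) -> int:
    """Classic full dynamic-programming table."""
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        dp[i][0] = i
    for j in range(n + 1):
        dp[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            dp[i][j] = min(dp[i - 1][j] + 1, dp[i][j - 1] + 1, dp[i - 1][j - 1] + cost)
    return dp[m][n]


def tokens_oracle(text: str) -> set[str]:
    out = set()
    for tok in norm(text).split(" "):
        tok = tok.strip(string.punctuation)
        if tok:
            out.add(tok)
    return out


def overlap_oracle(pred: str, gold: str) -> float:
    gt = tokens_oracle(gold)
    if not gt:
        return 0.0
    return len(gt & tokens_oracle(pred)) / len(gt)


def ece_oracle(
    confidences: list[float],
    scores: list[float],
    bins: list[tuple[float, float]],
) -> float:
    """Direct loop binning; last bin closed at the top."""
    assigned: list[list[tuple[float, float]]] = [[] for _ in bins]
    for c, s in zip(confidences, scores):
        for i, (lo, hi) in enumerate(bins):
            if lo <= c < hi or (i == len(bins) - 1 and c == hi):
                assigned[i].append((c, s))
                break
    total = sum(len(a) for a in assigned)
    if total == 0:
        return 0.0
    out = 0.0
    for pairs in assigned:
        if not pairs:
            continue
        mc = sum(c for c, _ in pairs) / len(pairs)
        ms = sum(s for _, s in pairs) / len(pairs)
        out += len(pairs) / total * abs(mc - ms)
    return out
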