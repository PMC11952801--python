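"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive and self-contained: no function from
the package under test is called, so agreement between the two routes is
meaningful evidence of correctness.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterator

# --- global alignment by exhaustive enumeration ----------------------------


def enumerate_alignments(a: str, b: str) -> Iterator[tuple[str, str]]:
    """Every global alignment of ``a`` and ``b`` as gapped string pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for rest_a, rest_b in enumerate_alignments(a[1:], b):
            yield a[0] + rest_a, "-" + rest_b
    if b:
        for rest_a, rest_b in enumerate_alignments(a, b[1:]):
            yield "-" + rest_a, b[0] + rest_b
    if a and b:
        for rest_a, rest_b in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + rest_a, b[0] + rest_b


def score_gapped_pair(
    ga: str,
    gb: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -0.5,
    gap_extend: float = -0.1,
) -> float:
    """Score one gapped pair; a gap run of length g costs open + (g-1)*extend."""
    total = 0.0
    run_a = run_b = 0
    for x, y in zip(ga, gb):
        if x == "-":
            run_a += 1
            run_b = 0
            total += gap_open if run_a == 1 else gap_extend
        elif y == "-":
            run_b += 1
            run_a = 0
            total += gap_open if run_b == 1 else gap_extend
        else:
            run_a = run_b = 0
            total += match if x == y else mismatch
    return total


def best_alignment_score(a: str, b: str, **kwargs) -> float:
    """Optimal global-alignment score by exhaustive enumeration."""
    return max(
        score_gapped_pair(ga, gb, **kwargs) for ga, gb in enumerate_alignments(a, b)
    )


# --- column conservation by direct formula evaluation -----------------------


def naive_relative_entropy(p: dict[str, float], q: dict[str, float]) -> float:
    return sum(
        pa * math.log2(pa / q[sym]) for sym, pa in p.items() if pa > 0
    )


def naive_jsd(p: dict[str, float], q: dict[str, float], lam: float = 0.5) -> float:
    symbols = set(p) | set(q)
    r = {s: lam * p.get(s, 0.0) + (1 - lam) * q.get(s, 0.0) for s in symbols}
    return lam * naive_relative_entropy(p, r) + (1 - lam) * naive_relative_entropy(q, r)


def naive_window_score(
    rows: list[str],
    site_column: int,
    background: dict[str, float],
    half_width: int = 5,
    lam: float = 0.5,
) -> float:
    """CS_p recomputed column by column from first principles."""
    length = len(rows[0])
    scores = []
    for c in range(max(0, site_column - half_width), min(length, site_column + half_width + 1)):
        if c == site_column:
            continue
        counts = Counter(row[c] for row in rows)
        p = {sym: n / len(rows) for sym, n in counts.items()}
        scores.append(naive_jsd(p, background, lam))
    return sum(scores) / len(scores)
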