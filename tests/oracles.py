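"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's vectorised/greedy code paths:
identity and the effective-sequence statistic are computed with plain
scalar loops, and matchings are found by exhaustive enumeration.
"""

from __future__ import annotations

import math


def scalar_identity(x: str, y: str, mode: str = "both_ungapped") -> float:
    """Scalar pairwise identity; independent of the library implementation."""
    assert len(x) == len(y)
    matches = 0
    both = 0
    for a, b in zip(x, y):
        if a != "-" and b != "-":
            both += 1
            if a == b and a != "X":
                matches += 1
    if mode == "full_length":
        return matches / len(x) if x else 0.0
    return matches / both if both else 0.0


def necs_bruteforce(
    rows: list[tuple[str, str]],
    threshold: float = 0.8,
    scaling: str = "inv_sqrt_L",
    identity_mode: str = "both_ungapped",
) -> float:
    """O(N^2) double-loop effective-sequence count over (seq_A, seq_B) rows."""
    n = len(rows)
    L = len(rows[0][0]) + len(rows[0][1])
    total = 0.0
    for i in range(n):
        neighbours = 0
        for j in range(n):
            if i == j:
                continue
            sa = scalar_identity(rows[i][0], rows[j][0], identity_mode)
            sb = scalar_identity(rows[i][1], rows[j][1], identity_mode)
            s = 0.0 if sa == 0 or sb == 0 else 2.0 / (1.0 / sa + 1.0 / sb)
            if s >= threshold:
                neighbours += 1
        total += 1.0 / (1.0 + neighbours)
    scale = 1.0 / math.sqrt(L) if scaling == "inv_sqrt_L" else 1.0 / L
    return scale * total


def _maximal_matchings(candidates: list[tuple]):
    """Yield every maximal one-to-one matching (as a frozenset of candidate
    indices) of a candidate list [(key, accA, accB), ...]."""

    results = set()

    def rec(chosen: frozenset, used_a: frozenset, used_b: frozenset):
        extended = False
        for idx, (_, a, b) in enumerate(candidates):
            if idx in chosen or a in used_a or b in used_b:
                continue
            extended = True
            rec(chosen | {idx}, used_a | {a}, used_b | {b})
        if not extended:
            results.add(chosen)

    rec(frozenset(), frozenset(), frozenset())
    return results


def lexmin_maximal_matching(candidates: list[tuple]) -> list[tuple]:
    """Among all maximal one-to-one matchings, the one whose ascending key
    sequence is lexicographically smallest.  Keys must be unique."""
    best = None
    for matching in _maximal_matchings(candidates):
        keys = sorted(candidates[i][0] for i in matching)
        if best is None or keys < best[0]:
            best = (keys, matching)
    if best is None:
        return []
    return sorted((candidates[i] for i in best[1]), key=lambda c: c[0])


def min_total_matchings(candidates: list[tuple]) -> list[list[tuple]]:
    """All maximum-cardinality matchings minimising the summed primary key
    (e.g. total gene distance); returned sorted by key."""
    matchings = _maximal_matchings(candidates)
    max_card = max((len(m) for m in matchings), default=0)
    best_total = None
    best = []
    for m in matchings:
        if len(m) != max_card:
            continue
        total = sum(candidates[i][0][0] for i in m)
        if best_total is None or total < best_total:
            best_total = total
            best = [m]
        elif total == best_total:
            best.append(m)
    return [sorted((candidates[i] for i in m), key=lambda c: c[0]) for m in best]


def rank_match_bruteforce(
    hits_a: list[tuple[str, float]], hits_b: list[tuple[str, float]]
) -> list[tuple[str, str]]:
    """Per-species rank matching on (accession, identity) lists: sort each
    side by identity descending (accession as tie-break) and zip."""
    sa = sorted(hits_a, key=lambda h: (-h[1], h[0]))
    sb = sorted(hits_b, key=lambda h: (-h[1], h[0]))
    return [(a[0], b[0]) for a, b in zip(sa, sb)]
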