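"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library routes they check: edit distance is
a plain quadratic dynamic program (the implementation uses edlib), and
MD points come from a quadratic next-same-label search (the
implementation uses a single reverse sweep).
"""

from __future__ import annotations


def edit_distance_dp(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) Levenshtein distance."""
    n = len(b)
    prev = list(range(n + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * n
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[n]


def divergence_dp(a: str, b: str) -> float:
    return edit_distance_dp(a, b) / max(len(a), len(b))


def md_points_brute(labels, max_period: int) -> list[tuple[int, int]]:
    """For each position, scan forward for the next equal label."""
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if labels[j] == labels[i]:
                if j - i <= max_period:
                    out.append((i, j - i))
                break
    return out
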