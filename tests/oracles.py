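"""Independent brute-force reference implementations used only by tests.

These deliberately use the slowest, most literal formulation of each
operation so they stay independent of the library's optimised code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def stitch_footprints_bruteforce(
    intervals: list[tuple[str, int, int]], distance: int
) -> set[tuple[str, int, int]]:
    """O(n²) transitive-closure merge of peak footprints."""
    items = [(c, s, e) for c, s, e in intervals]
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = items[i]
            cj, sj, ej = items[j]
            if ci != cj:
                continue
            gap = max(si, sj) - min(ei, ej)
            if gap <= distance:  # overlap gives negative gap
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = set()
    for members in groups.values():
        chrom = items[members[0]][0]
        out.add(
            (
                chrom,
                min(items[i][1] for i in members),
                max(items[i][2] for i in members),
            )
        )
    return out


def hockey_cutoff_bruteforce(signals) -> tuple[int, float]:
    """Exhaustive search over every candidate tangent line.

    For each 1-based rank x, the line of slope m = range/n through (x, s_x);
    picks the x minimising the count of points on or below the line (point j
    is on or below iff s_j − m·j ≤ s_x − m·x), ties to the largest x.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    m = (s[-1] - s[0]) / n
    best_x, best_count = None, None
    for x in range(1, n + 1):
        rhs = s[x - 1] - m * x
        count = 0
        for j in range(1, n + 1):
            if s[j - 1] - m * j <= rhs:
                count += 1
        if best_count is None or count < best_count or (
            count == best_count and x > best_x
        ):
            best_x, best_count = x, count
    return best_x, float(s[best_x - 1])


def window_score_naive(seq: str, matrix: np.ndarray) -> float:
    """Score one window by per-position lookup; N contributes 0."""
    total = 0.0
    for j, base in enumerate(seq):
        k = "ACGT".find(base)
        if k >= 0:
            total += matrix[j, k]
    return total


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def exhaustive_tail(int_matrix: np.ndarray, background, threshold: int) -> float:
    """P(int window score >= threshold) by enumerating all 4^w words."""
    bg = np.asarray(background, dtype=float)
    w = int_matrix.shape[0]
    total = 0.0
    for word in itertools.product(range(4), repeat=w):
        score = sum(int(int_matrix[j, b]) for j, b in enumerate(word))
        if score >= threshold:
            prob = 1.0
            for b in word:
                prob *= bg[b]
            total += prob
    return total


def circuitries_bruteforce(
    nodes: list[str],
    edges: set[tuple[str, str]],
    autoregulated: set[str],
    min_size: int = 2,
) -> set[frozenset]:
    """Power-set filtering: every fully interconnected autoregulated subset."""
    auto = [n for n in nodes if n in autoregulated]
    out = set()
    for k in range(min_size, len(auto) + 1):
        for combo in itertools.combinations(auto, k):
            if all(
                (a, b) in edges and (b, a) in edges
                for a, b in itertools.combinations(combo, 2)
            ):
                out.add(frozenset(combo))
    return out
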