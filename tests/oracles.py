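"""Independent brute-force oracles for the recurrence and alignment measures.

These deliberately use plain double loops and exhaustive enumeration so
they share no code with the implementations they check.
"""

from __future__ import annotations

import math


def oracle_recurrence_matrix(positions, eps):
    """O(n^2) double-loop recurrence matrix (inclusive threshold)."""
    n = len(positions)
    m = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            d = math.hypot(positions[i][0] - positions[j][0],
                           positions[i][1] - positions[j][1])
            m[i][j] = d <= eps
    return m


def oracle_recurrence_rate(m):
    n = len(m)
    r = sum(1 for i in range(n) for j in range(i + 1, n) if m[i][j])
    return 100.0 * 2.0 * r / (n * (n - 1))


def _upper_count(m):
    n = len(m)
    return sum(1 for i in range(n) for j in range(i + 1, n) if m[i][j])


def oracle_determinism(m, l_min=2):
    """Exhaustive diagonal-run scan over the strict upper triangle."""
    n = len(m)
    r = _upper_count(m)
    if r == 0:
        return 0.0
    on_lines = 0
    for k in range(1, n):
        cells = [(i, i + k) for i in range(n - k)]
        run = 0
        for idx, (i, j) in enumerate(cells):
            if m[i][j]:
                run += 1
            if not m[i][j] or idx == len(cells) - 1:
                if run >= l_min:
                    on_lines += run
                run = 0
    return 100.0 * on_lines / r


def oracle_laminarity(m, l_min=2):
    """Exhaustive row/column run scan.

    Runs include the self-recurrence cells; only strict-upper-triangle
    points are counted; denominator 2R.
    """
    n = len(m)
    r = _upper_count(m)
    if r == 0:
        return 0.0

    def scan(cells, count_if):
        total = 0
        run = []
        for idx, (i, j) in enumerate(cells):
            if m[i][j]:
                run.append((i, j))
            if not m[i][j] or idx == len(cells) - 1:
                if len(run) >= l_min:
                    total += sum(1 for c in run if count_if(c))
                run = []
        return total

    v = sum(scan([(i, j) for i in range(n)], lambda c: c[0] < c[1]) for j in range(n))
    h = sum(scan([(i, j) for j in range(n)], lambda c: c[1] > c[0]) for i in range(n))
    return 100.0 * (h + v) / (2.0 * r)


def oracle_alignment_cost(cost_matrix):
    """Minimum monotone-path cost by exhaustive recursion (small instances)."""
    ni = len(cost_matrix)
    nj = len(cost_matrix[0])

    def best(i, j):
        c = cost_matrix[i][j]
        if i == ni - 1 and j == nj - 1:
            return c
        options = []
        if i + 1 < ni and j + 1 < nj:
            options.append(best(i + 1, j + 1))
        if i + 1 < ni:
            options.append(best(i + 1, j))
        if j + 1 < nj:
            options.append(best(i, j + 1))
        return c + min(options)

    return best(0, 0)
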