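"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the package's algorithmic code paths: paths are
enumerated recursively, cross-correlations evaluated from the defining sum,
and the ICC mean squares accumulated with explicit loops.
"""

from __future__ import annotations

import math

import numpy as np


def cc_by_definition(x, y):
    """Cross-correlation sequence from the defining sum, 1-based transcribed."""
    x = list(map(float, x))
    y = list(map(float, y))
    m = len(x)
    out = []
    for w in range(1, 2 * m):
        k = w - m
        if k >= 0:
            out.append(sum(x[l + k] * y[l] for l in range(m - k)))
        else:
            kk = -k
            out.append(sum(y[l + kk] * x[l] for l in range(m - kk)))
    return np.array(out)


def enumerate_paths(m, n):
    """Every monotone contiguous path from (0,0) to (m-1,n-1)."""
    paths = []
    stack = [(0, 0)]

    def rec(i, j):
        if i == m - 1 and j == n - 1:
            paths.append(list(stack))
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < m and nj < n:
                stack.append((ni, nj))
                rec(ni, nj)
                stack.pop()

    rec(0, 0)
    return paths


def brute_dtw(x, y, max_length=None):
    """Minimal sqrt-sum-of-squares cost over enumerated paths."""
    x = list(map(float, x))
    y = list(map(float, y))
    best = math.inf
    for p in enumerate_paths(len(x), len(y)):
        if max_length is not None and len(p) > max_length:
            continue
        cost = sum((x[i] - y[j]) ** 2 for i, j in p)
        best = min(best, cost)
    return math.sqrt(best) if best < math.inf else math.inf


def anova_icc21(ratings):
    """ICC(2,1) from explicitly accumulated two-way ANOVA mean squares."""
    y = [list(map(float, row)) for row in ratings]
    n = len(y)
    k = len(y[0])
    grand = sum(sum(row) for row in y) / (n * k)
    subj = [sum(row) / k for row in y]
    rater = [sum(y[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((s - grand) ** 2 for s in subj)
    ss_cols = n * sum((r - grand) ** 2 for r in rater)
    ss_tot = sum((y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
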