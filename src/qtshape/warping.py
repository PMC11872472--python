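"""Dynamic time warping, plain and under a limited warping-path length.

Conventions (fixed for the whole package):

* local cost is the squared difference, aggregated by summation, and the
  reported distance is the square root of the aggregate;
* the step pattern is the symmetric ``{(1,0), (0,1), (1,1)}`` with no slope
  weighting;
* ties between equal-cost predecessors are broken diagonal first, then
  vertical (advance the first series), then horizontal, so returned paths
  are deterministic.

The length-limited variant (``ldtw``) minimizes the same cost over monotone
paths whose number of matched pairs does not exceed ``max_length``.  The DP
runs over states ``(i, j, path-length)``; because a path reaching ``(i, j)``
has length between ``max(i, j) + 1`` and ``max_length``, the length axis is
stored as a small "excess" offset, keeping memory at
``O(m * n * (max_length - max(m, n) + 1))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WarpingPath", "dtw", "ldtw", "default_max_length"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dep, fallback for safety

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@dataclass(frozen=True)
class WarpingPath:
    """A monotone, contiguous alignment between two series.

    ``pairs`` is an ``(P, 2)`` integer array of ``(i, j)`` index pairs,
    0-based into (first series, second series).
    """

    pairs: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.pairs.shape[0]

    def validate(self, m: int, n: int, max_length: int | None = None) -> None:
        """Assert boundary, monotonicity, unit steps and the length bound."""
        p = self.pairs
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
            raise AssertionError("path must be a non-empty (P, 2) array")
        if tuple(p[0]) != (0, 0) or tuple(p[-1]) != (m - 1, n - 1):
            raise AssertionError("path must run from (0,0) to (m-1,n-1)")
        steps = np.diff(p, axis=0)
        if steps.size and not (
            (steps >= 0).all() and (steps <= 1).all() and (steps.sum(axis=1) >= 1).all()
        ):
            raise AssertionError("path steps must increment i, j or both by 1")
        if max_length is not None and self.length > max_length:
            raise AssertionError(f"path length {self.length} exceeds bound {max_length}")


def default_max_length(m: int) -> int:
    """Default warping-path length bound: series length plus 10."""
    if m < 1:
        raise ValueError("series length must be >= 1")
    return int(m) + 10


@njit(cache=True)
def _dtw_fill(x, y):  # pragma: no cover - numba kernel, covered via dtw()
    m = x.shape[0]
    n = y.shape[0]
    big = np.inf
    acc = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            c = (x[i] - y[j]) ** 2
            if i == 0 and j == 0:
                acc[i, j] = c
            else:
                best = big
                if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                    best = acc[i - 1, j - 1]
                if i > 0 and acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if j > 0 and acc[i, j - 1] < best:
                    best = acc[i, j - 1]
                acc[i, j] = c + best
    return acc


def _check_inputs(x, y):
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("dtw inputs must be one-dimensional")
    if x.size == 0 or y.size == 0:
        raise ValueError("dtw inputs must be non-empty")
    return x, y


def dtw(x, y) -> tuple[float, WarpingPath]:
    """Unconstrained DTW distance and an optimal warping path."""
    x, y = _check_inputs(x, y)
    m, n = x.size, y.size
    acc = _dtw_fill(x, y)
    # Backtrack; preference on ties: diagonal, vertical, horizontal.
    i, j = m - 1, n - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        cands = []
        if i > 0 and j > 0:
            cands.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            cands.append((acc[i - 1, j], i - 1, j))
        if j > 0:
            cands.append((acc[i, j - 1], i, j - 1))
        best = min(c[0] for c in cands)
        for v, pi, pj in cands:
            if v == best:
                i, j = pi, pj
                break
        rev.append((i, j))
    pairs = np.array(rev[::-1], dtype=np.int64)
    return math.sqrt(max(acc[m - 1, n - 1], 0.0)), WarpingPath(pairs)


@njit(cache=True)
def _ldtw_fill(x, y, E):  # pragma: no cover - numba kernel, covered via ldtw()
    m = x.shape[0]
    n = y.shape[0]
    big = np.inf
    # D[e, i, j] = min cost over paths (0,0)->(i,j) of exactly
    # max(i, j) + 1 + e pairs.
    D = np.full((E + 1, m, n), big)
    D[0, 0, 0] = (x[0] - y[0]) ** 2
    for i in range(m):
        for j in range(n):
            if i == 0 and j == 0:
                continue
            c = (x[i] - y[j]) ** 2
            mx = i if i > j else j
            for e in range(E + 1):
                L = mx + 1 + e  # path length at this state
                best = big
                # diagonal: max drops by exactly 1 -> same excess
                if i > 0 and j > 0:
                    v = D[e, i - 1, j - 1]
                    if v < best:
                        best = v
                # vertical (i-1, j)
                if i > 0:
                    pmx = i - 1 if i - 1 > j else j
                    ep = L - 1 - pmx - 1
                    if 0 <= ep <= E:
                        v = D[ep, i - 1, j]
                        if v < best:
                            best = v
                # horizontal (i, j-1)
                if j > 0:
                    pmx = i if i > j - 1 else j - 1
                    ep = L - 1 - pmx - 1
                    if 0 <= ep <= E:
                        v = D[ep, i, j - 1]
                        if v < best:
                            best = v
                if best < big:
                    D[e, i, j] = c + best
    return D


def ldtw(x, y, max_length: int) -> tuple[float, WarpingPath]:
    """DTW restricted to warping paths of at most ``max_length`` pairs.

    ``max_length`` must be at least ``max(m, n)`` (the minimum feasible path
    length); values above ``m + n - 1`` are equivalent to unconstrained DTW
    and are clipped internally.
    """
    x, y = _check_inputs(x, y)
    m, n = x.size, y.size
    max_length = int(max_length)
    if max_length < max(m, n):
        raise ValueError(
            f"max_length={max_length} infeasible: minimum path length is {max(m, n)}"
        )
    eff = min(max_length, m + n - 1)
    E = eff - max(m, n)
    D = _ldtw_fill(x, y, E)
    final = D[:, m - 1, n - 1]
    e = int(np.argmin(final))  # ties -> smallest path length
    total = final[e]
    if not np.isfinite(total):
        raise RuntimeError("LDTW DP produced no feasible path")  # unreachable
    # Backtrack through (i, j, e) states; tie preference diag, vert, horiz.
    i, j = m - 1, n - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        mx = max(i, j)
        L = mx + 1 + e
        c = (x[i] - y[j]) ** 2
        cands = []
        if i > 0 and j > 0:
            cands.append((D[e, i - 1, j - 1], i - 1, j - 1, e))
        if i > 0:
            ep = L - 1 - max(i - 1, j) - 1
            if 0 <= ep <= E:
                cands.append((D[ep, i - 1, j], i - 1, j, ep))
        if j > 0:
            ep = L - 1 - max(i, j - 1) - 1
            if 0 <= ep <= E:
                cands.append((D[ep, i, j - 1], i, j - 1, ep))
        best = min(cand[0] for cand in cands)
        for v, pi, pj, pe in cands:
            if v == best:
                i, j, e = pi, pj, pe
                break
        rev.append((i, j))
    pairs = np.array(rev[::-1], dtype=np.int64)
    path = WarpingPath(pairs)
    path.validate(m, n, max_length)
    return math.sqrt(max(float(total), 0.0)), path
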