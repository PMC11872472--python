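"""K-shape clustering of z-normalized beats.

Assignment uses the shape-based distance; centroid update is the standard
shape extraction: members are aligned to the current centroid at their
optimal SBD shift and the new centroid is the leading eigenvector of the
centered sum of outer products (the maximizer of the squared-correlation
Rayleigh quotient), sign-disambiguated against the current centroid and
re-normalized.  The whole fit is restarted ``n_init`` times from seeded
initializations and the run with minimal inertia wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .errors import DegenerateSeriesError
from .shape_metrics import align_to, sbd

__all__ = [
    "ClusterModel",
    "init_centroids",
    "assign",
    "shape_extraction",
    "kshape_fit",
    "filter_small_clusters",
    "sbd_to_centroids",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 12
DEFAULT_N_INIT = 100
DEFAULT_MAX_ITER = 100
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray = field(repr=False)  # (k, L), z-normalized
    labels: np.ndarray = field(repr=False)  # (n,)
    inertia: float = np.inf
    n_iter: int = 0
    seed: int = 0
    inertia_history: list[float] = field(default_factory=list, repr=False)
    excluded: np.ndarray = field(default=None, repr=False)  # (n,) bool

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = np.zeros(self.labels.shape[0], dtype=bool)

    def cluster_sizes(self) -> np.ndarray:
        """Member counts per cluster, excluded beats not counted."""
        return np.bincount(self.labels[~self.excluded], minlength=self.k)

    def recompute_inertia(self, X: np.ndarray) -> float:
        d = np.array(
            [sbd(X[i], self.centroids[self.labels[i]]).distance for i in range(len(X))]
        )
        return float(np.sum(d**2))


def _znorm(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise DegenerateSeriesError("cannot z-normalize a constant centroid")
    return (v - v.mean()) / sd


def init_centroids(X: np.ndarray, k: int, rng_seed: int) -> np.ndarray:
    """Pick k distinct beats uniformly (seeded) as initial centroids."""
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} beats, got {n}")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(n, size=k, replace=False)
    return X[idx].copy()


def sbd_to_centroids(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """SBD distance matrix (n_beats, k) computed with batched FFTs.

    Equivalent to calling :func:`qtshape.shape_metrics.sbd` entry-wise; the
    maximal normalized cross-correlation does not depend on lag tie-breaks.
    """
    n, m = X.shape
    k = centroids.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * m - 1)))
    Xf = np.fft.rfft(X, nfft, axis=1)
    nx = np.linalg.norm(X, axis=1)
    dist = np.empty((n, k))
    for c in range(k):
        cf = np.fft.rfft(centroids[c], nfft)
        r = np.fft.irfft(Xf * np.conj(cf)[None, :], nfft, axis=1)
        # lags 0..m-1 live at [:, :m], lags -(m-1)..-1 at [:, nfft-m+1:]
        cc_max = np.maximum(r[:, :m].max(axis=1), r[:, nfft - m + 1 :].max(axis=1))
        denom = nx * np.linalg.norm(centroids[c])
        dist[:, c] = 1.0 - cc_max / denom
    return dist


def assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels by SBD; ties go to the lowest cluster index.

    Returns ``(labels, dist_to_own)``.
    """
    dist = sbd_to_centroids(X, centroids)
    labels = np.argmin(dist, axis=1)
    return labels, dist[np.arange(len(X)), labels]


def shape_extraction(members: np.ndarray, current_centroid: np.ndarray) -> np.ndarray:
    """New centroid minimizing total squared SBD of the aligned members."""
    members = np.atleast_2d(members)
    if members.shape[0] == 0:
        raise ValueError("shape extraction needs at least one member")
    L = members.shape[1]
    aligned = np.empty_like(members)
    for t, row in enumerate(members):
        res = sbd(current_centroid, row)
        aligned[t] = align_to(row, res.shift)
    S = aligned.T @ aligned
    # M = Q S Q with Q = I - 11^T / L (centering projector)
    col = S.mean(axis=0, keepdims=True)
    rowm = S.mean(axis=1, keepdims=True)
    M = S - col - rowm + S.mean()
    _, vec = eigh(M, subset_by_index=(L - 1, L - 1))
    v = vec[:, 0]
    try:
        plus = _znorm(v)
    except DegenerateSeriesError:
        raise DegenerateSeriesError("all members degenerate in shape extraction")
    minus = _znorm(-v)
    # Sign is arbitrary for an eigenvector; keep the one closer in SBD.
    if sbd(current_centroid, minus).distance < sbd(current_centroid, plus).distance:
        return minus
    return plus


def _reseed_empty(
    centroids: np.ndarray, labels: np.ndarray, dist: np.ndarray, X: np.ndarray
) -> None:
    """Give each empty cluster the beat farthest from its own centroid."""
    counts = np.bincount(labels, minlength=centroids.shape[0])
    order = np.argsort(-dist)  # farthest-first
    used = 0
    for c in np.flatnonzero(counts == 0):
        logger.warning("cluster %d became empty; reseeding with a far beat", c)
        centroids[c] = X[order[used]].copy()
        used += 1


def _single_run(
    X: np.ndarray, k: int, max_iter: int, seed: int
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    centroids = init_centroids(X, k, seed)
    labels, dist = assign(X, centroids)
    history = [float(np.sum(dist**2))]
    n_iter = 0
    for it in range(1, max_iter + 1):
        for c in range(k):
            mask = labels == c
            if not mask.any():
                continue  # handled after reassignment via reseeding
            centroids[c] = shape_extraction(X[mask], centroids[c])
        new_labels, dist = assign(X, centroids)
        _reseed_empty(centroids, new_labels, dist, X)
        history.append(float(np.sum(dist**2)))
        n_iter = it
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return labels, centroids, history[-1], n_iter, history


def kshape_fit(
    X: np.ndarray,
    k: int = DEFAULT_K,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-``n_init`` K-shape fit (run r uses sub-seed ``seed + r``)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a (n_beats, L) matrix")
    best = None
    for r in range(n_init):
        labels, centroids, inertia, n_iter, history = _single_run(
            X, k, max_iter, seed + r
        )
        if best is None or inertia < best.inertia:
            best = ClusterModel(
                k=k,
                centroids=centroids,
                labels=labels,
                inertia=inertia,
                n_iter=n_iter,
                seed=seed,
                inertia_history=history,
            )
    return best


def filter_small_clusters(
    model: ClusterModel, min_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> ClusterModel:
    """Mark beats of clusters with fewer than ``min_size`` members excluded.

    The cluster list itself is preserved; emptied clusters simply produce no
    template downstream.
    """
    sizes = model.cluster_sizes()
    for c in np.flatnonzero((sizes > 0) & (sizes < min_size)):
        logger.info("cluster %d has %d beats (< %d); excluding", c, sizes[c], min_size)
        model.excluded |= model.labels == c
    return model
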