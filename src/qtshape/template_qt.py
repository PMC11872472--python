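"""Template selection, outlier screening, fiducial transfer and QT math.

Per surviving cluster, the member beat closest (plain DTW) to the centroid
becomes the template; cluster members at or above the cluster's 90th
percentile of DTW distance are dropped.  Registered template fiducials are
transferred to each beat through its length-limited warping path: the QRS
onset takes the latest linked beat sample, the T end the earliest.  QT is
the onset-to-end interval in ms; QTcB divides by the square root of the
preceding RR in seconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .kshape import ClusterModel
from .preprocess import Beat, ExclusionReason
from .warping import WarpingPath, default_max_length, dtw, ldtw

__all__ = [
    "Template",
    "QtMeasurement",
    "centroid_dtw_distances",
    "select_templates",
    "exclude_outlier_beats",
    "register_fiducials",
    "transfer_fiducials",
    "compute_qt",
    "bazett",
    "measure_beats",
]

logger = logging.getLogger(__name__)

OUTLIER_PERCENTILE = 90.0


@dataclass
class Template:
    cluster_id: int
    beat_index: int  # index into the normalized-beat matrix
    samples: np.ndarray = field(repr=False)
    qrs_onset: int | None = None
    t_end: int | None = None

    def set_fiducials(self, qrs_onset: int, t_end: int) -> None:
        L = self.samples.shape[0]
        if not 0 <= qrs_onset < t_end <= L - 1:
            raise ValueError(
                f"cluster {self.cluster_id}: fiducials ({qrs_onset}, {t_end}) "
                f"violate 0 <= onset < t_end < {L}"
            )
        self.qrs_onset = int(qrs_onset)
        self.t_end = int(t_end)


@dataclass
class QtMeasurement:
    beat_index: int
    r_peak: int
    cluster_id: int
    qrs_onset: int
    t_end: int
    rr_prev_ms: float
    qt_ms: float
    qtcb_ms: float
    excluded: bool = False
    exclusion_reason: str = "none"


def centroid_dtw_distances(model: ClusterModel, X: np.ndarray) -> np.ndarray:
    """DTW distance from each beat to its own cluster centroid.

    Excluded beats get NaN.
    """
    d = np.full(X.shape[0], np.nan)
    for i in range(X.shape[0]):
        if model.excluded[i]:
            continue
        dist, _ = dtw(model.centroids[model.labels[i]], X[i])
        d[i] = dist
    return d


def select_templates(
    model: ClusterModel, X: np.ndarray, distances: np.ndarray | None = None
) -> list[Template]:
    """One template per non-empty surviving cluster: the member with the
    smallest DTW distance to the centroid (ties -> lowest beat index)."""
    if distances is None:
        distances = centroid_dtw_distances(model, X)
    templates: list[Template] = []
    for c in range(model.k):
        mask = (model.labels == c) & ~model.excluded
        members = np.flatnonzero(mask)
        if members.size == 0:
            logger.warning("cluster %d has no surviving beats; no template", c)
            continue
        best = members[np.argmin(distances[members])]  # argmin: first minimum
        templates.append(Template(cluster_id=c, beat_index=int(best), samples=X[best]))
    return templates


def exclude_outlier_beats(
    model: ClusterModel,
    distances: np.ndarray,
    percentile: float = OUTLIER_PERCENTILE,
) -> ClusterModel:
    """Drop beats at or above their cluster's distance percentile.

    The percentile uses linear interpolation between order statistics.  Two
    guards keep clusters usable: an all-equal-distance cluster is exempt,
    and exclusions are capped at ``ceil((1 - p/100) * size)`` beats, taken
    from the largest distances.
    """
    for c in range(model.k):
        members = np.flatnonzero((model.labels == c) & ~model.excluded)
        if members.size == 0:
            continue
        d = distances[members]
        if np.ptp(d) == 0:
            continue
        thr = np.percentile(d, percentile)
        over = members[d >= thr]
        cap = math.ceil((1.0 - percentile / 100.0) * members.size)
        if over.size > cap:
            order = np.argsort(-distances[over], kind="stable")
            over = over[order[:cap]]
        model.excluded[over] = True
    return model


def register_fiducials(
    templates: list[Template], fiducials: dict[int, tuple[int, int]]
) -> list[Template]:
    """Attach per-cluster registered fiducials to the templates."""
    missing = [t.cluster_id for t in templates if t.cluster_id not in fiducials]
    if missing:
        raise ConfigurationError(
            f"fiducial registration missing for clusters {sorted(missing)}"
        )
    for t in templates:
        onset, t_end = fiducials[t.cluster_id]
        t.set_fiducials(onset, t_end)
    return templates


def transfer_fiducials(template: Template, path: WarpingPath) -> tuple[int, int]:
    """Map template fiducials to beat samples through a warping path.

    With multiple links, the QRS onset takes the LATEST linked beat index
    and the T end the EARLIEST.
    """
    if template.qrs_onset is None or template.t_end is None:
        raise ConfigurationError(
            f"template for cluster {template.cluster_id} has no registered fiducials"
        )
    pairs = path.pairs
    on = pairs[pairs[:, 0] == template.qrs_onset, 1]
    te = pairs[pairs[:, 0] == template.t_end, 1]
    if on.size == 0 or te.size == 0:
        raise RuntimeError("warping path does not cover a fiducial index")
    return int(on.max()), int(te.min())


def compute_qt(qrs_onset_beat: int, t_end_beat: int, fs: float) -> float:
    """QT interval in ms; non-positive intervals return NaN (invalid)."""
    if t_end_beat <= qrs_onset_beat:
        return float("nan")
    return (t_end_beat - qrs_onset_beat) / fs * 1000.0


def bazett(qt_ms: float, rr_prev_ms: float) -> float:
    """Bazett heart-rate correction: QT / sqrt(RR in seconds)."""
    if rr_prev_ms <= 0:
        raise ValueError(f"rr_prev_ms must be positive, got {rr_prev_ms}")
    return qt_ms / math.sqrt(rr_prev_ms / 1000.0)


def measure_beats(
    templates: list[Template],
    model: ClusterModel,
    X: np.ndarray,
    beats: list[Beat],
    beat_positions: np.ndarray,
    fs: float,
    max_length_offset: int = 10,
) -> list[QtMeasurement]:
    """Transfer fiducials to every retained beat and compute QT / QTcB.

    ``beat_positions[t]`` maps row ``t`` of ``X`` back into ``beats``.
    Beats whose transferred interval is non-positive are flagged invalid
    rather than dropped silently.
    """
    by_cluster = {t.cluster_id: t for t in templates}
    out: list[QtMeasurement] = []
    L = X.shape[1]
    if max_length_offset == 10:
        max_length = default_max_length(L)
    else:
        max_length = L + max_length_offset
    max_length = min(max_length, 2 * L - 1)
    for t in range(X.shape[0]):
        if model.excluded[t]:
            continue
        template = by_cluster.get(int(model.labels[t]))
        if template is None:
            continue
        beat = beats[beat_positions[t]]
        if t == template.beat_index:
            onset, t_end = template.qrs_onset, template.t_end
        else:
            _, path = ldtw(template.samples, X[t], max_length)
            onset, t_end = transfer_fiducials(template, path)
        qt = compute_qt(onset, t_end, fs)
        valid = not math.isnan(qt)
        qtcb = bazett(qt, beat.rr_prev_ms) if valid and beat.rr_prev_ms > 0 else float("nan")
        out.append(
            QtMeasurement(
                beat_index=beat.beat_index,
                r_peak=beat.r_peak,
                cluster_id=int(model.labels[t]),
                qrs_onset=int(onset),
                t_end=int(t_end),
                rr_prev_ms=float(beat.rr_prev_ms),
                qt_ms=qt,
                qtcb_ms=qtcb,
                excluded=not valid,
                exclusion_reason="none" if valid else "invalid_interval",
            )
        )
    return out
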