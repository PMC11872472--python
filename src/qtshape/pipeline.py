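"""High-level orchestration shared by the CLI, the tests and the
acceptance script: filter -> extract -> exclude -> normalize -> cluster ->
template -> register -> transfer -> measure."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import PairedMeasurements
from .io_formats import EcgRecord
from .kshape import (
    DEFAULT_K,
    DEFAULT_MAX_ITER,
    DEFAULT_MIN_CLUSTER_SIZE,
    DEFAULT_N_INIT,
    ClusterModel,
    filter_small_clusters,
    kshape_fit,
)
from .preprocess import (
    Beat,
    FilterSpec,
    apply_rr_exclusions,
    extract_beats,
    lowpass_filter,
    normalize_beats,
)
from .template_qt import (
    OUTLIER_PERCENTILE,
    QtMeasurement,
    Template,
    centroid_dtw_distances,
    exclude_outlier_beats,
    measure_beats,
    register_fiducials,
    select_templates,
)

__all__ = ["PipelineConfig", "PipelineState", "run_pipeline", "truth_fiducials_for_templates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables, defaulting to the published operating point."""

    channel: int = 0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    k: int = DEFAULT_K
    n_init: int = DEFAULT_N_INIT
    max_iter: int = DEFAULT_MAX_ITER
    seed: int = 0
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    outlier_percentile: float = OUTLIER_PERCENTILE
    max_length_offset: int = 10
    pairing_tolerance_ms: float = 150.0


@dataclass
class PipelineState:
    record: EcgRecord
    beats: list[Beat]
    X: np.ndarray
    positions: np.ndarray  # X row -> index into beats
    model: ClusterModel | None = None
    distances: np.ndarray | None = None
    templates: list[Template] | None = None
    measurements: list[QtMeasurement] | None = None

    def counts(self) -> dict:
        reasons: dict[str, int] = {}
        for b in self.beats:
            if b.excluded:
                reasons[b.exclusion_reason.value] = (
                    reasons.get(b.exclusion_reason.value, 0) + 1
                )
        out = {
            "n_r_peaks": len(self.beats),
            "n_retained_beats": int(sum(not b.excluded for b in self.beats)),
            "excluded_by_reason": reasons,
        }
        if self.model is not None:
            out["cluster_sizes"] = self.model.cluster_sizes().tolist()
            out["n_clustering_excluded"] = int(self.model.excluded.sum())
        if self.measurements is not None:
            out["n_measured"] = len(self.measurements)
        return out


def preprocess_record(record: EcgRecord, config: PipelineConfig) -> PipelineState:
    """Filter the continuous record, cut beats, apply RR screens, z-score."""
    sig = lowpass_filter(record.signal[config.channel], record.fs, config.filter_spec)
    filtered = EcgRecord(
        record.record_id, sig[None, :], [record.channel_names[config.channel]],
        record.fs, record.r_peaks,
    )
    beats = apply_rr_exclusions(extract_beats(filtered))
    X, positions = normalize_beats(beats)
    return PipelineState(record=filtered, beats=beats, X=X, positions=positions)


def cluster_beats(state: PipelineState, config: PipelineConfig) -> PipelineState:
    k = min(config.k, state.X.shape[0])
    if k < config.k:
        logger.warning("only %d beats available; reducing k from %d", k, config.k)
    model = kshape_fit(
        state.X, k=k, n_init=config.n_init, max_iter=config.max_iter, seed=config.seed
    )
    state.model = filter_small_clusters(model, config.min_cluster_size)
    return state


def build_templates(state: PipelineState, config: PipelineConfig) -> PipelineState:
    """Select per-cluster templates, then screen DTW outlier beats."""
    state.distances = centroid_dtw_distances(state.model, state.X)
    state.templates = select_templates(state.model, state.X, state.distances)
    exclude_outlier_beats(state.model, state.distances, config.outlier_percentile)
    # A template must survive its own cluster's screen.
    for t in state.templates:
        state.model.excluded[t.beat_index] = False
    return state


def truth_fiducials_for_templates(
    state: PipelineState, truth: pd.DataFrame
) -> dict[int, tuple[int, int]]:
    """Template-window fiducials derived from generator ground truth.

    Stands in for the manual registration step when the record is
    synthetic: the template's source beat has known global fiducial
    indices, which are shifted into its extraction window.
    """
    fs = state.record.fs
    pre = int(round(0.120 * fs))
    L = state.X.shape[1]
    by_beat = truth.set_index("beat")
    out: dict[int, tuple[int, int]] = {}
    for t in state.templates:
        beat = state.beats[state.positions[t.beat_index]]
        row = by_beat.loc[beat.beat_index]
        start = beat.r_peak - pre
        onset = int(row["qrs_onset"]) - start
        t_end = int(row["t_end"]) - start
        if not 0 <= onset < t_end <= L - 1:
            raise ValueError(
                f"truth fiducials for beat {beat.beat_index} fall outside the window"
            )
        out[t.cluster_id] = (onset, t_end)
    return out


def measure(
    state: PipelineState,
    fiducials: dict[int, tuple[int, int]],
    config: PipelineConfig,
) -> PipelineState:
    register_fiducials(state.templates, fiducials)
    state.measurements = measure_beats(
        state.templates,
        state.model,
        state.X,
        state.beats,
        state.positions,
        state.record.fs,
        max_length_offset=config.max_length_offset,
    )
    return state


def run_pipeline(
    record: EcgRecord,
    config: PipelineConfig,
    fiducials: dict[int, tuple[int, int]] | None = None,
    truth: pd.DataFrame | None = None,
) -> PipelineState:
    """Run every stage; fiducials come from a registration dict or, for
    synthetic records, from the generator truth table."""
    state = preprocess_record(record, config)
    state = cluster_beats(state, config)
    state = build_templates(state, config)
    if fiducials is None:
        if truth is None:
            raise ValueError("need either registered fiducials or a truth table")
        fiducials = truth_fiducials_for_templates(state, truth)
    state = measure(state, fiducials, config)
    logger.info("pipeline counts: %s", state.counts())
    return state


def compare_to_truth(state: PipelineState, truth: pd.DataFrame) -> pd.DataFrame:
    """Join measurements with generator truth; adds ``qt_error_ms``."""
    meas = pd.DataFrame(
        [
            {
                "beat": m.beat_index,
                "qt_ms": m.qt_ms,
                "qtcb_ms": m.qtcb_ms,
                "cluster_id": m.cluster_id,
                "excluded": m.excluded,
            }
            for m in state.measurements
        ]
    )
    df = meas.merge(truth[["beat", "qt_true_ms", "morphology"]], on="beat", how="inner")
    df["qt_error_ms"] = df["qt_ms"] - df["qt_true_ms"]
    return df


def measurements_to_pairs(df: pd.DataFrame) -> PairedMeasurements:
    """Truth-vs-measured pairs from a :func:`compare_to_truth` frame."""
    keep = ~df["excluded"].astype(bool)
    return PairedMeasurements(
        df.loc[keep, "qt_true_ms"].to_numpy(), df.loc[keep, "qt_ms"].to_numpy()
    )
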