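"""Beat extraction, RR-based exclusion, low-pass filtering, z-normalization.

A heartbeat window runs from 120 ms before its R peak to 80 ms before the
next R peak, standardized to 1600 ms: longer windows are truncated, shorter
ones are tail-padded with the average of the raw window's two endpoint
samples.  Beats are then screened on the preceding RR interval (< 300 ms,
> 2000 ms, or outside 70-130 % of the following RR) before z-normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSeriesError
from .io_formats import EcgRecord

__all__ = [
    "FilterSpec",
    "ExclusionReason",
    "Beat",
    "NormalizedBeat",
    "lowpass_filter",
    "extract_beats",
    "apply_rr_exclusions",
    "znormalize",
    "normalize_beats",
    "beat_window_length",
]

logger = logging.getLogger(__name__)

PRE_R_MS = 120.0  # window start relative to R peak
POST_NEXT_R_MS = 80.0  # window end relative to the next R peak
BEAT_MS = 1600.0  # standardized beat duration

RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0
RR_RATIO_MIN = 0.70
RR_RATIO_MAX = 1.30


class ExclusionReason(str, Enum):
    NONE = "none"
    RR_SHORT = "rr_short"
    RR_LONG = "rr_long"
    RR_RATIO = "rr_ratio"
    FIRST_OR_LAST = "first_or_last"
    OUT_OF_BOUNDS = "out_of_bounds"
    DEGENERATE = "degenerate"
    DTW_OUTLIER = "dtw_outlier"
    SMALL_CLUSTER = "small_cluster"


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass design constraints, checked on the net zero-phase response."""

    passband_edge_hz: float = 50.0
    stopband_edge_hz: float = 60.0
    max_passband_loss_db: float = 3.0
    min_stopband_loss_db: float = 40.0

    def __post_init__(self):
        if not 0 < self.passband_edge_hz < self.stopband_edge_hz:
            raise ValueError("need 0 < passband_edge < stopband_edge")
        if self.max_passband_loss_db <= 0 or self.min_stopband_loss_db <= 0:
            raise ValueError("loss specifications must be positive dB")


@dataclass
class Beat:
    beat_index: int
    r_peak: int
    samples: np.ndarray = field(repr=False)
    rr_prev_ms: float = float("nan")
    rr_next_ms: float = float("nan")
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def exclude(self, reason: ExclusionReason) -> None:
        self.excluded = True
        self.exclusion_reason = reason


@dataclass(frozen=True)
class NormalizedBeat:
    """Z-scored beat with the raw mean/SD retained for inversion."""

    z: np.ndarray = field(repr=False)
    mu: float = 0.0
    sigma: float = 1.0


def beat_window_length(fs: float) -> int:
    """Fixed beat length in samples: round(1.6 s * fs)."""
    return int(round(BEAT_MS / 1000.0 * fs))


def design_lowpass(fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Minimum-order elliptic SOS meeting ``spec`` after two-pass filtering.

    Each dB figure is halved at design time because forward-backward
    application doubles the response in dB.
    """
    if fs <= 2 * spec.stopband_edge_hz:
        raise ValueError(
            f"fs={fs} too low for stopband edge {spec.stopband_edge_hz} Hz"
        )
    return sps.iirdesign(
        wp=spec.passband_edge_hz,
        ws=spec.stopband_edge_hz,
        gpass=spec.max_passband_loss_db / 2.0,
        gstop=spec.min_stopband_loss_db / 2.0,
        ftype="ellip",
        output="sos",
        fs=fs,
    )


def lowpass_filter(x, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase low-pass filtering of a continuous signal.

    Applied forward-backward so fiducial landmarks suffer no group delay;
    the passband/stopband constraints hold on the combined response.
    """
    x = np.asarray(x, dtype=float)
    sos = design_lowpass(fs, spec)
    return sps.sosfiltfilt(sos, x, axis=-1)


def extract_beats(record: EcgRecord, channel: int = 0) -> list[Beat]:
    """Cut one fixed-length beat per R peak.

    The first and last beats lack one RR neighbor and are flagged
    ``first_or_last``; a beat whose window starts before the record is
    flagged ``out_of_bounds``.  Interior windows are ``[r_i - 0.120 fs,
    r_{i+1} - 0.080 fs)``, truncated or endpoint-average padded to L.
    """
    r = np.asarray(record.r_peaks, dtype=int)
    if r.size < 3:
        raise ValueError("need at least 3 R peaks (boundary beats are excluded)")
    sig = np.asarray(record.signal, dtype=float)
    if sig.ndim == 2:
        sig = sig[channel]
    fs = record.fs
    L = beat_window_length(fs)
    pre = int(round(PRE_R_MS / 1000.0 * fs))
    post = int(round(POST_NEXT_R_MS / 1000.0 * fs))
    n = sig.size

    beats: list[Beat] = []
    for i, ri in enumerate(r):
        rr_prev = (ri - r[i - 1]) / fs * 1000.0 if i > 0 else float("nan")
        rr_next = (r[i + 1] - ri) / fs * 1000.0 if i < r.size - 1 else float("nan")
        start = int(ri) - pre
        end = int(r[i + 1]) - post if i < r.size - 1 else start + L
        beat = Beat(
            beat_index=i,
            r_peak=int(ri),
            samples=np.zeros(L),
            rr_prev_ms=rr_prev,
            rr_next_ms=rr_next,
        )
        if i == 0 or i == r.size - 1:
            beat.exclude(ExclusionReason.FIRST_OR_LAST)
        if start < 0 or end > n or end <= start:
            if not beat.excluded:
                logger.warning("beat %d window [%d, %d) out of record bounds", i, start, end)
                beat.exclude(ExclusionReason.OUT_OF_BOUNDS)
            beats.append(beat)
            continue
        raw = sig[start:end]
        if raw.size >= L:
            samples = raw[:L].copy()
        else:
            pad_value = (raw[0] + raw[-1]) / 2.0
            samples = np.concatenate([raw, np.full(L - raw.size, pad_value)])
        beat.samples = samples
        beats.append(beat)
    return beats


def apply_rr_exclusions(beats: list[Beat]) -> list[Beat]:
    """Flag beats with unreliable preceding RR context (strict inequalities).

    Thresholds: rr_prev < 300 ms, rr_prev > 2000 ms, or
    rr_prev/rr_next outside the open interval (0.70, 1.30).
    """
    for b in beats:
        if b.excluded:
            continue
        if b.rr_prev_ms < RR_MIN_MS:
            b.exclude(ExclusionReason.RR_SHORT)
        elif b.rr_prev_ms > RR_MAX_MS:
            b.exclude(ExclusionReason.RR_LONG)
        else:
            ratio = b.rr_prev_ms / b.rr_next_ms
            if ratio < RR_RATIO_MIN or ratio > RR_RATIO_MAX:
                b.exclude(ExclusionReason.RR_RATIO)
    return beats


def znormalize(samples) -> NormalizedBeat:
    """Standardize to zero mean and unit (population) standard deviation."""
    x = np.asarray(getattr(samples, "samples", samples), dtype=float)
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # population SD (divide by n)
    if sigma == 0.0:
        raise DegenerateSeriesError("constant beat cannot be z-normalized")
    return NormalizedBeat(z=(x - mu) / sigma, mu=mu, sigma=sigma)


def normalize_beats(beats: list[Beat]) -> tuple[np.ndarray, np.ndarray]:
    """Z-normalize every retained beat into a matrix.

    Returns ``(X, idx)`` where row ``X[t]`` is the z-scored beat whose
    position in ``beats`` is ``idx[t]``.  Degenerate (constant) beats are
    flagged excluded with a warning and left out.
    """
    rows, idx = [], []
    for i, b in enumerate(beats):
        if b.excluded:
            continue
        try:
            nb = znormalize(b.samples)
        except DegenerateSeriesError:
            logger.warning("beat %d is constant; excluding as degenerate", b.beat_index)
            b.exclude(ExclusionReason.DEGENERATE)
            continue
        rows.append(nb.z)
        idx.append(i)
    X = np.array(rows) if rows else np.empty((0, 0))
    return X, np.asarray(idx, dtype=int)
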