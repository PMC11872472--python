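"""Synthetic ECG with analytic ground-truth fiducials.

Beats are sums of Gaussian bumps (P, Q, R, S, T and optionally a second T
lobe) placed relative to the R peak, so the true QRS onset and T end are
model parameters rather than estimates.  A record is a tiling of per-beat
segments ``[R_b - 120 ms, R_{b+1} - 120 ms)``; each segment can receive a
smooth monotone time warp (endpoints fixed) and additive Gaussian noise,
with fiducials and the R-peak location warped consistently.

T morphology variants: normal, inverted (sign-flipped T), biphasic (two
opposite-sign lobes), flat (near-zero amplitude) and tall (doubled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import EcgRecord

__all__ = [
    "GaussianWave",
    "BeatShapeSpec",
    "SynthRecordConfig",
    "default_shape",
    "render_beat",
    "generate_record",
    "truth_qt",
]

PRE_R_MS = 120.0  # segment lead-in before each R peak

MORPHOLOGIES = ("normal", "inverted", "biphasic", "flat", "tall")


@dataclass(frozen=True)
class GaussianWave:
    amplitude_mv: float
    center_ms: float  # relative to the R peak
    width_ms: float  # Gaussian sigma


@dataclass(frozen=True)
class BeatShapeSpec:
    waves: tuple[GaussianWave, ...]
    qrs_onset_ms: float  # negative: before R
    t_end_ms: float  # positive: after R
    morphology: str = "normal"

    def __post_init__(self):
        if not self.qrs_onset_ms < 0 < self.t_end_ms:
            raise ValueError("need qrs_onset_ms < 0 < t_end_ms")

    @property
    def qt_ms(self) -> float:
        return self.t_end_ms - self.qrs_onset_ms


_BASE_WAVES = (
    GaussianWave(0.15, -210.0, 28.0),  # P
    GaussianWave(-0.12, -28.0, 9.0),  # Q
    GaussianWave(1.20, 0.0, 11.0),  # R
    GaussianWave(-0.25, 28.0, 10.0),  # S
)
_T_NORMAL = GaussianWave(0.35, 255.0, 48.0)


def default_shape(morphology: str = "normal") -> BeatShapeSpec:
    """Stock beat shape for each T-wave morphology class."""
    if morphology == "normal":
        t_waves = (_T_NORMAL,)
    elif morphology == "inverted":
        t_waves = (replace(_T_NORMAL, amplitude_mv=-_T_NORMAL.amplitude_mv),)
    elif morphology == "biphasic":
        t_waves = (
            GaussianWave(0.25, 225.0, 38.0),
            GaussianWave(-0.25, 285.0, 38.0),
        )
    elif morphology == "flat":
        t_waves = (replace(_T_NORMAL, amplitude_mv=0.04),)
    elif morphology == "tall":
        t_waves = (replace(_T_NORMAL, amplitude_mv=2 * _T_NORMAL.amplitude_mv),)
    else:
        raise ValueError(f"unknown morphology {morphology!r}; choose from {MORPHOLOGIES}")
    return BeatShapeSpec(
        waves=_BASE_WAVES + t_waves,
        qrs_onset_ms=-48.0,
        t_end_ms=360.0,
        morphology=morphology,
    )


@dataclass(frozen=True)
class SynthRecordConfig:
    n_beats: int = 900
    mean_rr_ms: float = 1000.0
    rr_jitter_sd_ms: float = 0.0
    class_mixture: dict = field(default_factory=lambda: {"normal": 1.0})
    noise_sd_mv: float = 0.0
    warp_strength: float = 1.0  # max local time stretch factor, >= 1
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class mixture must sum to 1, got {total}")
        if self.warp_strength < 1.0:
            raise ValueError("warp_strength must be >= 1")


def _make_warp(n: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth monotone map phi of [0, n-1] onto itself, endpoints fixed.

    Built from positive knot increments in [1/strength, strength]
    (cumulative-sum construction), interpolated to per-sample resolution and
    rescaled to hit the endpoints.
    """
    if strength == 1.0:
        return np.arange(n, dtype=float)
    n_knots = max(4, n // 25)
    incr = rng.uniform(1.0 / strength, strength, size=n_knots)
    knots_y = np.concatenate([[0.0], np.cumsum(incr)])
    knots_y *= (n - 1) / knots_y[-1]
    knots_x = np.linspace(0.0, n - 1, n_knots + 1)
    phi = np.interp(np.arange(n, dtype=float), knots_x, knots_y)
    if np.any(np.diff(phi) <= 0):  # cannot happen with positive increments
        raise RuntimeError("constructed warp is not monotone")
    return phi


def _warp_position(p: float, phi: np.ndarray) -> float:
    """Index q with phi(q) = p, by inverse interpolation."""
    return float(np.interp(p, phi, np.arange(phi.size, dtype=float)))


def render_beat(
    spec: BeatShapeSpec,
    rr_ms: float,
    fs: float,
    warp_strength: float = 1.0,
    noise_sd_mv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int, int, int]:
    """Render one beat segment.

    The segment spans ``[-120 ms, rr_ms - 120 ms)`` around the R peak.
    Returns ``(samples, r_idx, qrs_onset_idx, t_end_idx)`` with indices
    valid after warping.
    """
    if not 300.0 <= rr_ms <= 2000.0:
        raise ValueError(f"rr_ms must lie in [300, 2000], got {rr_ms}")
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(rr_ms / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0 - PRE_R_MS  # time relative to R
    samples = np.zeros(n)
    for w in spec.waves:
        samples += w.amplitude_mv * np.exp(-0.5 * ((t_ms - w.center_ms) / w.width_ms) ** 2)

    def to_idx(ms_from_r: float) -> float:
        return (ms_from_r + PRE_R_MS) / 1000.0 * fs

    r_pos = to_idx(0.0)
    onset_pos = to_idx(spec.qrs_onset_ms)
    t_end_pos = to_idx(spec.t_end_ms)
    if warp_strength > 1.0:
        phi = _make_warp(n, warp_strength, rng)
        samples = np.interp(phi, np.arange(n, dtype=float), samples)
        r_pos = _warp_position(r_pos, phi)
        onset_pos = _warp_position(onset_pos, phi)
        t_end_pos = _warp_position(t_end_pos, phi)
    if noise_sd_mv > 0.0:
        samples = samples + rng.normal(0.0, noise_sd_mv, size=n)
    return samples, int(round(r_pos)), int(round(onset_pos)), int(round(t_end_pos))


def generate_record(
    config: SynthRecordConfig, record_id: str = "synth"
) -> tuple[EcgRecord, pd.DataFrame]:
    """Generate a beat train plus its per-beat ground-truth table.

    The truth table has columns ``beat``, ``r_peak``, ``qrs_onset``,
    ``t_end``, ``morphology`` and ``qt_true_ms`` (global sample indices).
    Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in classes], dtype=float)
    shapes = {c: default_shape(c) for c in classes}

    rr = rng.normal(config.mean_rr_ms, config.rr_jitter_sd_ms, size=config.n_beats)
    rr = np.clip(rr, 300.0, 2000.0)
    drawn = rng.choice(len(classes), size=config.n_beats, p=probs)

    segments = []
    truth_rows = []
    offset = 0
    for b in range(config.n_beats):
        cls = classes[drawn[b]]
        seg, r_idx, onset_idx, t_end_idx = render_beat(
            shapes[cls],
            float(rr[b]),
            config.fs,
            warp_strength=config.warp_strength,
            noise_sd_mv=config.noise_sd_mv,
            rng=rng,
        )
        segments.append(seg)
        truth_rows.append(
            {
                "beat": b,
                "r_peak": offset + r_idx,
                "qrs_onset": offset + onset_idx,
                "t_end": offset + t_end_idx,
                "morphology": cls,
                "qt_true_ms": (t_end_idx - onset_idx) / config.fs * 1000.0,
            }
        )
        offset += seg.size
    # Flat tail so the last beat window stays inside the record.
    tail = int(round(1.7 / 1.0 * config.fs))
    segments.append(np.zeros(tail))
    signal = np.concatenate(segments)
    truth = pd.DataFrame(truth_rows)
    record = EcgRecord(
        record_id=record_id,
        signal=signal[None, :],
        channel_names=["synth"],
        fs=config.fs,
        r_peaks=truth["r_peak"].to_numpy(),
    )
    return record, truth


def truth_qt(truth: pd.DataFrame, fs: float | None = None) -> pd.Series:
    """Per-beat true QT in ms, recomputed from the fiducial indices."""
    if fs is None:
        # qt_true_ms was stored at generation time; recompute needs fs
        return truth["qt_true_ms"]
    return (truth["t_end"] - truth["qrs_onset"]) / fs * 1000.0
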