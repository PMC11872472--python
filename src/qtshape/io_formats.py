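"""Domain records and on-disk contracts: WFDB signals/annotations and the
CSV files carrying fiducial registrations and QT measurements.

Sample indices are 0-based everywhere; windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import wfdb_io
from .errors import ParseError

__all__ = [
    "EcgRecord",
    "ExpertAnnotation",
    "read_wfdb_record",
    "read_fiducial_annotations",
    "read_fiducial_csv",
    "write_fiducial_csv",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "beat_index",
    "r_peak",
    "cluster_id",
    "qrs_onset",
    "t_end",
    "rr_prev_ms",
    "qt_ms",
    "qtcb_ms",
    "excluded",
    "exclusion_reason",
]


@dataclass
class EcgRecord:
    """Continuous multi-channel ECG with sampling rate and R-peak indices."""

    record_id: str
    signal: np.ndarray = field(repr=False)  # (n_channels, n_samples), mV
    channel_names: list[str]
    fs: float
    r_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = self.signal.shape[1]
        if self.r_peaks.size:
            if self.r_peaks.min() < 0 or self.r_peaks.max() >= n:
                raise ValueError("r_peaks must lie within [0, n_samples)")
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_r_peaks(self, r_peaks) -> "EcgRecord":
        return EcgRecord(
            self.record_id, self.signal, list(self.channel_names), self.fs, r_peaks
        )


@dataclass(frozen=True)
class ExpertAnnotation:
    """One manually annotated beat: R reference, QRS onset and T end."""

    beat_ref: int
    qrs_onset: int
    t_end: int

    def __post_init__(self):
        if not self.qrs_onset < self.t_end:
            raise ValueError(
                f"qrs_onset ({self.qrs_onset}) must precede t_end ({self.t_end})"
            )


def read_wfdb_record(path, channel: int = 0) -> EcgRecord:
    """Read one channel of a WFDB record, in mV.

    ``r_peaks`` is left empty; attach R peaks from an annotation file or a
    detector with :meth:`EcgRecord.with_r_peaks`.
    """
    sig, header = wfdb_io.read_signals(str(path))
    if not 0 <= channel < header.n_sig:
        raise ValueError(
            f"channel {channel} out of range for {header.n_sig}-channel record"
        )
    return EcgRecord(
        record_id=header.record_name,
        signal=sig[channel : channel + 1],
        channel_names=[header.signals[channel].description],
        fs=header.fs,
    )


def _annotations_from_wfdb(path) -> list[ExpertAnnotation]:
    """Assemble (R, QRS onset, T end) triples from a .q1c-style stream.

    QRS onset is the '(' immediately preceding a beat symbol; T end is the
    ')' that follows a 't' symbol after that beat.
    """
    entries = wfdb_io.read_annotations(str(path))
    out: list[ExpertAnnotation] = []
    dropped = 0
    pending_open: int | None = None
    current: tuple[int, int] | None = None  # (r_sample, onset)
    t_seen = False
    for sample, code in entries:
        if code == wfdb_io.ANN_WFON:
            pending_open = sample
        elif code in wfdb_io.BEAT_CODES:
            if current is not None:
                dropped += 1  # previous beat never got its T end
            current = (sample, pending_open) if pending_open is not None else None
            if current is None:
                dropped += 1
            pending_open = None
            t_seen = False
        elif code == wfdb_io.ANN_TWAVE:
            t_seen = True
        elif code == wfdb_io.ANN_WFOFF and t_seen:
            if current is not None:
                r, onset = current
                if onset is not None and onset < sample:
                    out.append(ExpertAnnotation(r, onset, sample))
                else:
                    dropped += 1
                current = None
            t_seen = False
    if current is not None:
        dropped += 1
    if dropped:
        logger.info("%s: dropped %d beats lacking a complete fiducial pair", path, dropped)
    return out


def _annotations_from_csv(path) -> list[ExpertAnnotation]:
    out: list[ExpertAnnotation] = []
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return out
    header = [h.strip().lower() for h in lines[0].split(",")]
    required = {"r_peak", "qrs_onset", "t_end"}
    if not required.issubset(header):
        raise ParseError(f"{path}:1: expected columns {sorted(required)}, got {header}")
    col = {name: header.index(name) for name in required}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = line.split(",")
        try:
            r = int(toks[col["r_peak"]])
            onset = int(toks[col["qrs_onset"]])
            t_end = int(toks[col["t_end"]])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed row {line!r}") from exc
        if t_end <= onset:
            logger.warning("%s:%d: t_end <= qrs_onset, row rejected", path, lineno)
            continue
        out.append(ExpertAnnotation(r, onset, t_end))
    return out


def read_fiducial_annotations(path) -> list[ExpertAnnotation]:
    """Read expert fiducials from a CSV or a WFDB annotation file.

    CSV dialect: header ``r_peak,qrs_onset,t_end`` with integer 0-based
    sample indices.  Any other extension is parsed as a binary MIT
    annotation file.
    """
    if str(path).lower().endswith(".csv"):
        return _annotations_from_csv(path)
    return _annotations_from_wfdb(path)


def read_fiducial_csv(path) -> dict[int, tuple[int, int]]:
    """Per-cluster template fiducials: ``{cluster_id: (qrs_onset, t_end)}``."""
    df = pd.read_csv(path)
    required = {"cluster_id", "qrs_onset", "t_end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    out: dict[int, tuple[int, int]] = {}
    for _, row in df.iterrows():
        cid = int(row["cluster_id"])
        onset, t_end = int(row["qrs_onset"]), int(row["t_end"])
        if t_end <= onset:
            raise ParseError(
                f"{path}: cluster {cid}: t_end ({t_end}) must exceed qrs_onset ({onset})"
            )
        out[cid] = (onset, t_end)
    return out


def write_fiducial_csv(path, fiducials: dict[int, tuple[int, int]]) -> None:
    rows = [
        {"cluster_id": cid, "qrs_onset": onset, "t_end": t_end}
        for cid, (onset, t_end) in sorted(fiducials.items())
    ]
    pd.DataFrame(rows, columns=["cluster_id", "qrs_onset", "t_end"]).to_csv(
        path, index=False
    )


def write_measurements(measurements, path) -> None:
    """Write QT measurements as CSV, ordered by beat index.

    Accepts any iterable of objects or mappings exposing the fields in
    ``MEASUREMENT_COLUMNS``.
    """
    rows = []
    for m in measurements:
        get = m.get if isinstance(m, dict) else lambda k, _m=m: getattr(_m, k)
        rows.append({c: get(c) for c in MEASUREMENT_COLUMNS})
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if len(df):
        df = df.sort_values("beat_index", kind="stable")
    df.to_csv(path, index=False, float_format="%.6f")


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
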