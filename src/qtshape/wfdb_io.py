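"""Minimal WFDB codec: .hea/.dat signals (formats 16 and 212) and MIT
annotation files.

Only the subset of the WFDB spec needed for two-channel Holter records and
their waveform-boundary annotations is implemented.  Values are converted to
physical units as ``(adu - baseline) / gain`` with the usual default gain of
200 adu/mV when the header stores 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import ParseError

__all__ = [
    "SignalInfo",
    "Header",
    "read_header",
    "read_signals",
    "write_record",
    "read_annotations",
    "write_annotations",
    "ANN_NORMAL",
    "ANN_PWAVE",
    "ANN_TWAVE",
    "ANN_WFON",
    "ANN_WFOFF",
    "BEAT_CODES",
]

DEFAULT_GAIN = 200.0

# MIT annotation type codes (ecgcodes.h subset).
ANN_NORMAL = 1
ANN_PWAVE = 24
ANN_TWAVE = 27
ANN_UWAVE = 29
ANN_WFON = 39  # '('
ANN_WFOFF = 40  # ')'
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

# Codes that mark a QRS complex (beat) rather than a wave or marker.
BEAT_CODES = frozenset(range(1, 14)) | {25, 34, 35, 38, 41}


@dataclass(frozen=True)
class SignalInfo:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


@dataclass(frozen=True)
class Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: tuple[SignalInfo, ...]


def _strip_ext(path: str) -> str:
    base, ext = os.path.splitext(path)
    return base if ext in {".hea", ".dat"} else path


def read_header(path: str) -> Header:
    """Parse a .hea file (``path`` may omit the extension)."""
    base = _strip_ext(str(path))
    hea = base + ".hea"
    with open(hea, "r") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{hea}: empty header")
    top = lines[0].split()
    if len(top) < 2:
        raise ParseError(f"{hea}: malformed record line: {lines[0]!r}")
    record_name = top[0].split("/")[0]
    n_sig = int(top[1])
    fs = float(top[2].split("/")[0]) if len(top) > 2 else 250.0
    n_samples = int(top[3]) if len(top) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        toks = ln.split()
        if len(toks) < 2:
            raise ParseError(f"{hea}: malformed signal line: {ln!r}")
        fname = toks[0]
        fmt = int(toks[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = DEFAULT_GAIN, 0, "mV"
        if len(toks) > 2:
            gtok = toks[2]
            if "/" in gtok:
                gtok, units = gtok.split("/", 1)
            if "(" in gtok:
                gtok, btok = gtok.split("(", 1)
                baseline = int(btok.rstrip(")"))
            gain = float(gtok)
            if gain == 0:
                gain = DEFAULT_GAIN
        # token 4 (ADC zero) acts as the baseline when no '(baseline)' given
        if len(toks) > 4 and "(" not in toks[2]:
            try:
                baseline = int(toks[4])
            except ValueError:
                pass
        desc = " ".join(toks[8:]) if len(toks) > 8 else f"sig{len(signals)}"
        signals.append(SignalInfo(fname, fmt, gain, baseline, units, desc))
    if len(signals) != n_sig:
        raise ParseError(f"{hea}: expected {n_sig} signal lines, found {len(signals)}")
    return Header(record_name, n_sig, fs, n_samples, tuple(signals))


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    raw = raw.astype(np.int64)
    n_triplets = raw.size // 3
    trip = raw[: n_triplets * 3].reshape(-1, 3)
    s1 = trip[:, 0] | ((trip[:, 1] & 0x0F) << 8)
    s2 = trip[:, 2] | ((trip[:, 1] & 0xF0) << 4)
    out = np.empty(n_triplets * 2, dtype=np.int64)
    out[0::2] = s1
    out[1::2] = s2
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_values]


def read_signals(path: str) -> tuple[np.ndarray, Header]:
    """Read all channels of a record in physical units (mV).

    Returns ``(signal, header)`` with ``signal`` of shape
    ``(n_sig, n_samples)``.
    """
    base = _strip_ext(str(path))
    header = read_header(base)
    dirname = os.path.dirname(base)
    # All signals of the records we handle share one .dat file.
    dat_names = {s.file_name for s in header.signals}
    if len(dat_names) != 1:
        raise ParseError(f"{base}: multi-file records are not supported")
    dat = os.path.join(dirname, dat_names.pop())
    fmt = header.signals[0].fmt
    raw = np.fromfile(dat, dtype=np.uint8)
    n_sig = header.n_sig
    if fmt == 16:
        adus = raw.view(np.int16).astype(np.int64)
    elif fmt == 212:
        n_total = header.n_samples * n_sig if header.n_samples else (raw.size // 3) * 2
        adus = _decode_212(raw, n_total)
    else:
        raise ParseError(f"{base}: unsupported WFDB format {fmt}")
    n_samples = adus.size // n_sig
    if header.n_samples:
        n_samples = min(n_samples, header.n_samples)
    adus = adus[: n_samples * n_sig].reshape(n_samples, n_sig).T
    sig = np.empty((n_sig, n_samples), dtype=float)
    for c, info in enumerate(header.signals):
        sig[c] = (adus[c] - info.baseline) / info.gain
    return sig, header


def write_record(
    base_path: str,
    signal_mv: np.ndarray,
    fs: float,
    channel_names: list[str] | None = None,
    gain: float = DEFAULT_GAIN,
) -> None:
    """Write a format-16 .hea/.dat pair from a physical-units signal."""
    sig = np.atleast_2d(np.asarray(signal_mv, dtype=float))
    n_sig, n_samples = sig.shape
    base = _strip_ext(str(base_path))
    name = os.path.basename(base)
    if channel_names is None:
        channel_names = [f"ch{c}" for c in range(n_sig)]
    adus = np.rint(sig * gain)
    if np.abs(adus).max(initial=0) > 32767:
        raise ValueError("signal exceeds int16 range at the chosen gain")
    inter = adus.T.astype("<i2")  # sample-major interleave
    inter.tofile(base + ".dat")
    fs_txt = f"{fs:g}"
    gain_txt = f"{gain:g}"
    with open(base + ".hea", "w") as fh:
        fh.write(f"{name} {n_sig} {fs_txt} {n_samples}\n")
        for c in range(n_sig):
            fh.write(
                f"{name}.dat 16 {gain_txt}(0)/mV 16 0 0 0 0 {channel_names[c]}\n"
            )


def read_annotations(path: str) -> list[tuple[int, int]]:
    """Read a MIT annotation file as ``[(sample, type_code), ...]``.

    ``path`` is the full annotation file path (e.g. ``record.q1c``).
    NUM/SUB/CHN/AUX modifiers are consumed and discarded; SKIP entries
    advance the running time.
    """
    raw = np.fromfile(str(path), dtype=np.uint8)
    out: list[tuple[int, int]] = []
    t = 0
    i = 0
    n = raw.size
    while i + 1 < n:
        b0, b1 = int(raw[i]), int(raw[i + 1])
        i += 2
        code = b1 >> 2
        interval = ((b1 & 0x03) << 8) | b0
        if code == 0 and interval == 0:
            break  # end of file
        if code == _SKIP:
            if i + 3 >= n:
                raise ParseError(f"{path}: truncated SKIP at byte {i - 2}")
            hi = int(raw[i]) | (int(raw[i + 1]) << 8)
            lo = int(raw[i + 2]) | (int(raw[i + 3]) << 8)
            i += 4
            t += (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)  # aux string, padded to even
            continue
        t += interval
        out.append((t, code))
    return out


def write_annotations(path: str, entries: list[tuple[int, int]]) -> None:
    """Write ``[(sample, type_code), ...]`` as a MIT annotation file."""
    entries = sorted(entries)
    buf = bytearray()
    prev = 0
    for sample, code in entries:
        delta = int(sample) - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if delta > 1023:
            buf += bytes([0, _SKIP << 2])
            buf += int(delta >> 16).to_bytes(2, "little")
            buf += int(delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        buf += bytes([delta & 0xFF, ((int(code) & 0x3F) << 2) | ((delta >> 8) & 0x03)])
        prev = int(sample)
    buf += bytes([0, 0])
    with open(str(path), "wb") as fh:
        fh.write(buf)
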