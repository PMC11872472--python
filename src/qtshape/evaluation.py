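"""Agreement statistics between reference and candidate QT measurements.

Implements Shrout-Fleiss ICC(2,1) (two-way random effects, absolute
agreement, single measures) with the F-based 95 % confidence interval,
Bland-Altman bias / limits of agreement, Pearson correlation, and the
morphology-stratified difference table.  Differences are always
candidate minus reference (machine minus specialist).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QtShapeError
from .io_formats import ExpertAnnotation
from .template_qt import QtMeasurement

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "pair_beats",
    "icc_2_1",
    "bland_altman",
    "BlandAltman",
    "morphology_table",
    "agreement_report",
]

logger = logging.getLogger(__name__)

MORPHOLOGY_CLASSES = ("normal", "inverted", "biphasic", "flat", "tall")
DEFAULT_PAIRING_TOLERANCE_MS = 150.0


@dataclass
class PairedMeasurements:
    """Matched (reference, candidate) values in ms for one record."""

    reference_ms: np.ndarray
    candidate_ms: np.ndarray
    morphology_label: str | None = None
    n_reference_unmatched: int = 0
    n_candidate_unmatched: int = 0

    def __post_init__(self):
        self.reference_ms = np.asarray(self.reference_ms, dtype=float)
        self.candidate_ms = np.asarray(self.candidate_ms, dtype=float)
        if self.reference_ms.shape != self.candidate_ms.shape:
            raise ValueError("reference and candidate must have equal length")

    @property
    def n(self) -> int:
        return self.reference_ms.size

    @property
    def differences(self) -> np.ndarray:
        return self.candidate_ms - self.reference_ms


@dataclass
class BlandAltman:
    bias: float
    diff_sd: float
    loa: tuple[float, float]
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


@dataclass
class AgreementReport:
    icc_2_1: float
    icc_ci95: tuple[float, float]
    bias: float
    diff_sd: float
    loa: tuple[float, float]
    pearson_r: float
    n: int
    per_morphology: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "icc_2_1": self.icc_2_1,
            "icc_ci95": list(self.icc_ci95),
            "bias_ms": self.bias,
            "diff_sd_ms": self.diff_sd,
            "loa_ms": list(self.loa),
            "pearson_r": self.pearson_r,
            "n_pairs": self.n,
        }
        if self.per_morphology is not None:
            out["per_morphology"] = self.per_morphology.to_dict(orient="records")
        return out


def pair_beats(
    reference: list[ExpertAnnotation],
    candidate: list[QtMeasurement],
    fs: float,
    tolerance_ms: float = DEFAULT_PAIRING_TOLERANCE_MS,
    morphology_label: str | None = None,
) -> PairedMeasurements:
    """One-to-one matching of annotated and measured beats by R proximity.

    Candidates flagged excluded are never matched; matches farther apart
    than ``tolerance_ms`` are rejected.  Raises if no beat pairs up.
    """
    cands = [m for m in candidate if not m.excluded]
    tol = tolerance_ms / 1000.0 * fs
    edges = []  # (|dr|, ref_idx, cand_idx)
    for a, ann in enumerate(reference):
        for b, m in enumerate(cands):
            dr = abs(m.r_peak - ann.beat_ref)
            if dr <= tol:
                edges.append((dr, a, b))
    edges.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    ref_vals, cand_vals = [], []
    for _, a, b in edges:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        ann = reference[a]
        ref_vals.append((ann.t_end - ann.qrs_onset) / fs * 1000.0)
        cand_vals.append(cands[b].qt_ms)
    if not ref_vals:
        raise QtShapeError("no beats could be paired within tolerance")
    n_ref_um = len(reference) - len(used_a)
    n_cand_um = len(cands) - len(used_b)
    if n_ref_um or n_cand_um:
        logger.info(
            "pairing dropped %d reference and %d candidate beats", n_ref_um, n_cand_um
        )
    return PairedMeasurements(
        np.array(ref_vals),
        np.array(cand_vals),
        morphology_label=morphology_label,
        n_reference_unmatched=n_ref_um,
        n_candidate_unmatched=n_cand_um,
    )


def icc_2_1(
    reference, candidate, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with its F-based confidence interval for two raters.

    The two-way ANOVA mean squares are computed directly from the n x 2
    data matrix; the CI follows the Shrout-Fleiss / McGraw-Wong formulas
    with a Satterthwaite df for the lower/upper F quantiles.
    """
    y = np.column_stack(
        [np.asarray(reference, dtype=float), np.asarray(candidate, dtype=float)]
    )
    n, k = y.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    grand = y.mean()
    subj = y.mean(axis=1)
    rater = y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()
    ss_rows = k * ((subj - grand) ** 2).sum()
    ss_cols = n * ((rater - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: no variance in either rater")
    icc = (msr - mse) / denom

    # Confidence interval (McGraw & Wong case 2A, single measures).
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return float(icc), (1.0, 1.0) if icc == 1.0 else (float("nan"), float("nan"))
    if a * msc + b * mse == 0:
        return float(icc), (float("nan"), float("nan"))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def bland_altman(reference, candidate) -> BlandAltman:
    """Bias, SD of differences and 95 % limits of agreement.

    Differences are candidate - reference; the SD uses the n-1 divisor.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diffs = cand - ref
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        diff_sd=sd,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        means=(ref + cand) / 2.0,
        diffs=diffs,
    )


def morphology_table(
    record_pairs: dict[str, PairedMeasurements], labels: dict[str, str]
) -> pd.DataFrame:
    """Mean (SD) of candidate-minus-reference differences per morphology.

    ``labels`` maps record id to a morphology class; every record must be
    labeled.  A final "all" row pools every pair.  Empty classes are
    omitted.
    """
    missing = [rid for rid in record_pairs if rid not in labels]
    if missing:
        raise QtShapeError(f"records without morphology label: {sorted(missing)}")
    by_class: dict[str, list[np.ndarray]] = {}
    for rid, pairs in record_pairs.items():
        by_class.setdefault(labels[rid], []).append(pairs.differences)
    rows = []
    ordered = [m for m in MORPHOLOGY_CLASSES if m in by_class] + sorted(
        set(by_class) - set(MORPHOLOGY_CLASSES)
    )
    for morph in ordered:
        d = np.concatenate(by_class[morph])
        rows.append(
            {
                "morphology": morph,
                "n": d.size,
                "bias_ms": float(d.mean()),
                "sd_ms": float(d.std(ddof=1)) if d.size > 1 else 0.0,
            }
        )
    pooled = np.concatenate([p.differences for p in record_pairs.values()])
    rows.append(
        {
            "morphology": "all",
            "n": pooled.size,
            "bias_ms": float(pooled.mean()),
            "sd_ms": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["morphology", "n", "bias_ms", "sd_ms"])


def agreement_report(
    pairs: PairedMeasurements,
    record_pairs: dict[str, PairedMeasurements] | None = None,
    labels: dict[str, str] | None = None,
) -> AgreementReport:
    """Full agreement summary for one pooled set of pairs."""
    icc, ci = icc_2_1(pairs.reference_ms, pairs.candidate_ms)
    ba = bland_altman(pairs.reference_ms, pairs.candidate_ms)
    if np.std(pairs.reference_ms) == 0 or np.std(pairs.candidate_ms) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(pairs.reference_ms, pairs.candidate_ms)[0, 1])
    table = None
    if record_pairs is not None and labels is not None:
        table = morphology_table(record_pairs, labels)
    return AgreementReport(
        icc_2_1=icc,
        icc_ci95=ci,
        bias=ba.bias,
        diff_sd=ba.diff_sd,
        loa=ba.loa,
        pearson_r=r,
        n=pairs.n,
        per_morphology=table,
    )
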