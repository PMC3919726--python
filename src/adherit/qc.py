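"""Plate- and study-level assay quality statistics.

A screening plate is judged by how cleanly its positive controls (a
high-adhesion Trisomy 21 lymphoblastoid line) separate from its negative
controls (the low-adhesion Ramos Burkitt-lymphoma line):

* ``CV``  — per-sample replicate coefficient of variation, 100 * sd / mean
  (sample sd, n-1 denominator; replicate counts are small, typically 8).
* ``Z'``  — 1 - 3(sigma_pos + sigma_neg) / |mu_pos - mu_neg|
  (Zhang, Chung & Oldenburg 1999).  Z' > 0.5 marks an excellent assay and,
  with equal control sds, corresponds to a 12-sd band separation.
* ``SNR`` — (mu_pos - mu_neg) / sigma_neg by default; a pooled-sd variant
  (mu_pos - mu_neg) / sqrt(sigma_pos^2 + sigma_neg^2) is available.

Default gates: Z' >= 0.5 and every per-sample CV <= 10 %.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateDataError, InsufficientDataError
from .plate_io import PlateLayout, PlateReadingSet

__all__ = [
    "ControlSummary", "QCGates", "QCReport", "coefficient_of_variation",
    "z_prime", "signal_to_noise", "composite_z_prime", "qc_plate", "qc_study",
]


@dataclass(frozen=True)
class ControlSummary:
    """Mean/sd/count of positive- and negative-control signals (RFU or %)."""

    mu_pos: float
    sd_pos: float
    n_pos: int
    mu_neg: float
    sd_neg: float
    n_neg: int

    def __post_init__(self):
        if self.sd_pos < 0 or self.sd_neg < 0:
            raise ValueError("control sds must be non-negative")
        if self.n_pos < 2 or self.n_neg < 2:
            raise InsufficientDataError(
                "need >=2 wells per control group for sds to be defined"
            )

    @classmethod
    def from_values(cls, positive: Sequence[float],
                    negative: Sequence[float]) -> "ControlSummary":
        pos = np.asarray(positive, dtype=float)
        neg = np.asarray(negative, dtype=float)
        if pos.size < 2 or neg.size < 2:
            raise InsufficientDataError(
                f"need >=2 control wells per group, got {pos.size} positive "
                f"and {neg.size} negative"
            )
        return cls(mu_pos=float(pos.mean()), sd_pos=float(pos.std(ddof=1)),
                   n_pos=int(pos.size), mu_neg=float(neg.mean()),
                   sd_neg=float(neg.std(ddof=1)), n_neg=int(neg.size))


def coefficient_of_variation(values: Iterable[float]) -> float:
    """Replicate CV in percent: 100 * sample sd / mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"CV needs >=2 replicates, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("CV inputs must be finite")
    mean = arr.mean()
    if mean == 0:
        raise DegenerateDataError("CV undefined: replicate mean is zero")
    return float(100.0 * arr.std(ddof=1) / mean)


def z_prime(controls: ControlSummary) -> float:
    """Z'-factor: 1 - 3(sd_pos + sd_neg) / |mu_pos - mu_neg|; always <= 1."""
    sep = abs(controls.mu_pos - controls.mu_neg)
    if sep == 0:
        raise DegenerateDataError(
            "Z' undefined: positive and negative control means coincide"
        )
    return float(1.0 - 3.0 * (controls.sd_pos + controls.sd_neg) / sep)


def signal_to_noise(controls: ControlSummary, method: str = "neg_sd") -> float:
    """Control signal-to-noise ratio.

    ``neg_sd`` (default): (mu_pos - mu_neg) / sd_neg — the classic screening
    S/N.  ``pooled``: (mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2).
    """
    diff = controls.mu_pos - controls.mu_neg
    if method == "neg_sd":
        if controls.sd_neg == 0:
            raise DegenerateDataError("SNR undefined: negative-control sd is 0")
        return float(diff / controls.sd_neg)
    if method == "pooled":
        denom = math.hypot(controls.sd_pos, controls.sd_neg)
        if denom == 0:
            raise DegenerateDataError("SNR undefined: both control sds are 0")
        return float(diff / denom)
    raise ValueError(f"unknown SNR method {method!r}")


def _pool(summaries: Sequence[tuple[float, float, int]]) -> tuple[float, float, int]:
    """Pool (mean, sd, n) triples into a pooled mean/sd/n.

    The pooled variance is (within-plate SS + between-plate SS) over the
    pooled within-plate df, Sum(n_i - 1), so plates with identical controls
    pool to themselves while shifted plate means inflate the pooled sd.
    """
    n_tot = sum(n for _, _, n in summaries)
    mean = sum(n * m for m, _, n in summaries) / n_tot
    ss = sum((n - 1) * s ** 2 + n * (m - mean) ** 2 for m, s, n in summaries)
    sd = math.sqrt(ss / sum(n - 1 for _, _, n in summaries))
    return mean, sd, n_tot


def composite_z_prime(per_plate: Sequence[ControlSummary]) -> float:
    """Study-wide Z' from the pooled control wells of every usable plate.

    Pooling is exact (reconstructed from per-plate means, sds and counts), so
    shifted per-plate control means inflate the pooled sds and the composite
    is never better than the plates it pools.
    """
    usable = list(per_plate)
    if not usable:
        raise InsufficientDataError("no plates with valid controls")
    mu_p, sd_p, n_p = _pool([(c.mu_pos, c.sd_pos, c.n_pos) for c in usable])
    mu_n, sd_n, n_n = _pool([(c.mu_neg, c.sd_neg, c.n_neg) for c in usable])
    return z_prime(ControlSummary(mu_pos=mu_p, sd_pos=sd_p, n_pos=n_p,
                                  mu_neg=mu_n, sd_neg=sd_n, n_neg=n_n))


@dataclass(frozen=True)
class QCGates:
    """Pass/fail thresholds.

    A plate passes when Z' >= ``min_zprime`` and the median per-sample
    replicate CV is <= ``max_cv_percent``.  The median is the gated summary
    because with 8 replicates the sample CV of an in-spec line overshoots
    its true value often enough that a worst-case gate would discard most
    plates at the assay's own operating point; the full per-sample CV
    distribution is reported alongside.
    """

    min_zprime: float = 0.5
    max_cv_percent: float = 10.0


@dataclass
class QCReport:
    """Per-plate quality report on the post-wash control signals."""

    plate_id: str
    cv_by_sample: dict = field(default_factory=dict)
    zprime: float = float("nan")
    snr: float = float("nan")
    passed: bool = False
    gates: QCGates = field(default_factory=QCGates)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gates"] = asdict(self.gates)
        return d

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def control_summary_for_plate(readings: PlateReadingSet, plate_id: str,
                              read_stage: str = "wash3") -> ControlSummary:
    pos = readings.rfu_values(plate_id=plate_id, role="positive_control",
                              read_stage=read_stage)
    neg = readings.rfu_values(plate_id=plate_id, role="negative_control",
                              read_stage=read_stage)
    return ControlSummary.from_values(pos, neg)


def qc_plate(readings: PlateReadingSet, plate_id: str,
             gates: QCGates = QCGates(), read_stage: str = "wash3") -> QCReport:
    """Compute CVs, Z' and SNR for one plate and apply the gates."""
    controls = control_summary_for_plate(readings, plate_id, read_stage)
    zp = z_prime(controls)
    snr = signal_to_noise(controls)

    cvs: dict[str, float] = {}
    plate = readings.subset(plate_id=plate_id, read_stage=read_stage, role="test")
    for sid in sorted({r.sample_id for r in plate}):
        vals = plate.rfu_values(sample_id=sid)
        if len(vals) >= 2:
            cvs[sid] = coefficient_of_variation(vals)

    passed = zp >= gates.min_zprime and (
        not cvs or float(np.median(list(cvs.values()))) <= gates.max_cv_percent
    )
    return QCReport(plate_id=plate_id, cv_by_sample=cvs, zprime=zp, snr=snr,
                    passed=passed, gates=gates)


def qc_study(readings: PlateReadingSet, layouts: Sequence[PlateLayout],
             gates: QCGates = QCGates(),
             read_stage: str = "wash3") -> tuple[list[QCReport], float]:
    """Per-plate reports plus the study-wide composite Z'.

    Plates whose controls cannot be summarized (too few wells) contribute no
    report and are excluded from the composite.
    """
    reports, summaries = [], []
    for layout in layouts:
        try:
            summaries.append(
                control_summary_for_plate(readings, layout.plate_id, read_stage))
            reports.append(qc_plate(readings, layout.plate_id, gates, read_stage))
        except InsufficientDataError:
            continue
    return reports, composite_z_prime(summaries)
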