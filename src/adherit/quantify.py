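"""From raw well fluorescence to per-cell-line adhesion phenotypes.

The assay loads a known number of Calcein-labelled cells per well (50,000 by
default) on an endothelial monolayer, washes three times, and reads
fluorescence before washing and after the third wash.  Two phenotype scales
are derived per cell line:

* ``% input RFU`` = 100 * RFU(after wash 3) / RFU(before wash) — the primary
  readout;
* ``% adherent cells`` — the post-wash RFU inverted through a four-parameter
  logistic (4PL) standard curve fitted to wells of known cell number, as a
  percentage of loaded cells.

Cross-plate batch effects are removed by standardizing each sample to the
positive control (Trisomy 21 line) on its own plate; a plate-wide gain
multiplies sample and control alike and cancels in the ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (CurveFitError, DegenerateDataError,
                         InsufficientDataError, OutOfRangeError)
from .plate_io import PlateLayout, PlateReadingSet

DEFAULT_LOADED_CELLS = 50_000.0  # cells added per well


def four_pl(x, a, d, c, b):
    """4PL response d + (a - d) / (1 + (x/c)^b); a = zero-cell asymptote."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class FourPLCurve:
    """Fitted four-parameter logistic standard curve (cells/well <-> RFU).

    ``a`` and ``d`` are the asymptotes at zero and infinite cells (RFU),
    ``c`` the inflection point (cells/well), ``b`` the slope factor.  The
    curve is strictly monotone between its asymptotes, so inversion is exact.
    """

    a: float
    d: float
    c: float
    b: float
    residual_sd: float = 0.0
    n_points: int = 0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("inflection point c must be positive")
        if self.b == 0:
            raise ValueError("slope factor b must be nonzero")

    def evaluate(self, cells):
        return four_pl(cells, self.a, self.d, self.c, self.b)

    def invert(self, rfu: float) -> float:
        """Unique preimage x = c * ((a-d)/(y-d) - 1)^(1/b) of an RFU value.

        Raises :class:`OutOfRangeError` for values on or beyond either
        asymptote — no extrapolation.
        """
        lo, hi = sorted((self.a, self.d))
        if not (lo < rfu < hi):
            which = "a (zero-cell)" if abs(rfu - self.a) <= abs(rfu - self.d) \
                else "d (saturation)"
            raise OutOfRangeError(
                f"RFU {rfu:g} outside open asymptote interval ({lo:g}, {hi:g}); "
                f"nearest asymptote: {which}"
            )
        ratio = (self.a - self.d) / (rfu - self.d) - 1.0
        return float(self.c * ratio ** (1.0 / self.b))

    def to_dict(self) -> dict:
        return {"a": self.a, "d": self.d, "c": self.c, "b": self.b,
                "residual_sd": self.residual_sd, "n_points": self.n_points}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FourPLCurve":
        return cls(**{k: d[k] for k in ("a", "d", "c", "b")},
                   residual_sd=d.get("residual_sd", 0.0),
                   n_points=d.get("n_points", 0))

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def fit_four_pl(known_cells: Sequence[float],
                rfu: Sequence[float]) -> FourPLCurve:
    """Least-squares 4PL fit with a fixed, deterministic initialization.

    Start values: ``a``/``d`` from the RFU at the smallest/largest cell
    number, ``c`` at the geometric midpoint of the cell range, ``b`` = 1.
    """
    x = np.asarray(known_cells, dtype=float)
    y = np.asarray(rfu, dtype=float)
    if x.shape != y.shape:
        raise ValueError("known_cells and rfu must have equal length")
    if np.unique(x).size < 4:
        raise InsufficientDataError(
            f"4PL fit needs >=4 distinct cell numbers, got {np.unique(x).size}"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("cell numbers must be positive and rfu finite")

    order = np.argsort(x)
    a0 = float(y[order[0]])
    d0 = float(y[order[-1]])
    c0 = float(np.sqrt(x.min() * x.max()))
    p0 = [a0, d0, c0, 1.0]
    try:
        popt, _ = optimize.curve_fit(
            four_pl, x, y, p0=p0, maxfev=20_000,
            bounds=([-np.inf, -np.inf, 1e-12, -50.0],
                    [np.inf, np.inf, np.inf, 50.0]),
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise CurveFitError(f"4PL fit did not converge: {exc}",
                            best_params=p0) from exc
    resid = y - four_pl(x, *popt)
    dof = max(x.size - 4, 1)
    return FourPLCurve(a=float(popt[0]), d=float(popt[1]), c=float(popt[2]),
                       b=float(popt[3]),
                       residual_sd=float(np.sqrt(np.sum(resid ** 2) / dof)),
                       n_points=int(x.size))


def percent_input_rfu(pre_wash_rfu: float, post_wash3_rfu: float) -> float:
    """100 * RFU(after third wash) / RFU(before wash)."""
    if not pre_wash_rfu > 0:
        raise DegenerateDataError(
            f"pre-wash RFU must be positive, got {pre_wash_rfu!r}"
        )
    if post_wash3_rfu < 0:
        raise ValueError("post-wash RFU must be non-negative")
    return float(100.0 * post_wash3_rfu / pre_wash_rfu)


def percent_adherent(curve: FourPLCurve, post_wash3_rfu: float,
                     loaded_cells: float = DEFAULT_LOADED_CELLS) -> float:
    """Adherent cells (from the standard curve) as % of loaded cells."""
    if not loaded_cells > 0:
        raise ValueError("loaded_cells must be positive")
    return float(100.0 * curve.invert(post_wash3_rfu) / loaded_cells)


def standardize_to_control(sample_mean: float,
                           positive_control_mean: float) -> float:
    """Adhesion ratio of a sample to the positive control on the same plate."""
    if not positive_control_mean > 0:
        raise DegenerateDataError(
            f"positive-control mean must be positive, got {positive_control_mean!r}"
        )
    return float(sample_mean / positive_control_mean)


@dataclass(frozen=True)
class CrossPlateResult:
    """One-way ANOVA of standardized coefficients across plates."""

    applicable: bool
    p_value: Optional[float] = None
    f_statistic: Optional[float] = None
    reason: Optional[str] = None


def cross_plate_consistency(values_by_plate: Mapping[str, Sequence[float]]
                            ) -> CrossPlateResult:
    """Test whether a sample's standardized values differ between plates.

    One-way ANOVA F-test across plate groups.  A single plate, or zero
    within-plate variance everywhere, yields a flagged not-applicable result
    instead of a p-value.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_plate.values()]
    if len(groups) < 2:
        return CrossPlateResult(applicable=False, reason="single plate")
    if any(g.size < 2 for g in groups):
        return CrossPlateResult(applicable=False,
                                reason="a plate has <2 replicates")
    if all(g.std(ddof=1) == 0 for g in groups):
        return CrossPlateResult(applicable=False,
                                reason="zero within-plate variance")
    f, p = stats.f_oneway(*groups)
    return CrossPlateResult(applicable=True, p_value=float(p),
                            f_statistic=float(f))


# ---------------------------------------------------------------------------
# study-level quantification


@dataclass
class AdhesionPhenotype:
    """Replicate-aggregated adhesion of one cell line."""

    sample_id: str
    n_replicates: int
    pct_input_rfu_mean: float
    pct_input_rfu_sd: float
    cv_percent: float
    standardized_coefficient: float
    pct_adherent_mean: Optional[float] = None
    plate_ids: tuple = ()
    flagged_over_100: bool = False


def _per_well_percent_input(readings: PlateReadingSet, plate_id: str,
                            role: str, sample_id: Optional[str] = None
                            ) -> list[float]:
    """Pair pre_wash/wash3 reads per well and return % input values."""
    pre = {r.well: r.rfu for r in readings.subset(
        plate_id=plate_id, role=role, read_stage="pre_wash", sample_id=sample_id)}
    post = {r.well: r.rfu for r in readings.subset(
        plate_id=plate_id, role=role, read_stage="wash3", sample_id=sample_id)}
    return [percent_input_rfu(pre[w], post[w]) for w in pre if w in post]


def quantify_study(readings: PlateReadingSet, layouts: Sequence[PlateLayout],
                   curves: Optional[Mapping[str, FourPLCurve]] = None,
                   loaded_cells: float = DEFAULT_LOADED_CELLS,
                   exclude_plates: Sequence[str] = ()) -> pd.DataFrame:
    """Build the per-sample phenotype table.

    For every test sample on every usable plate: per-well % input RFU, the
    replicate mean/sd/CV, the ratio to the plate's positive-control mean,
    and (when a standard curve is supplied for the plate, or one study-wide
    curve under key ``""``) the mean % adherent cells.  Samples spanning
    plates are averaged across plates.  Plates listed in ``exclude_plates``
    (e.g. QC failures) contribute nothing.
    """
    curves = curves or {}
    rows: dict[str, dict] = {}
    for layout in layouts:
        pid = layout.plate_id
        if pid in exclude_plates:
            continue
        pos_vals = _per_well_percent_input(readings, pid, "positive_control")
        pos_mean = float(np.mean(pos_vals)) if pos_vals else np.nan
        curve = curves.get(pid, curves.get("", None))
        for sid in layout.samples_with_role("test"):
            pct = _per_well_percent_input(readings, pid, "test", sid)
            if not pct:
                continue
            adherent = None
            if curve is not None:
                post = [r.rfu for r in readings.subset(
                    plate_id=pid, role="test", read_stage="wash3",
                    sample_id=sid)]
                adherent = [percent_adherent(curve, y, loaded_cells)
                            for y in post]
            entry = rows.setdefault(sid, {"pct": [], "adherent": [],
                                          "ratios": [], "plates": []})
            entry["pct"].extend(pct)
            if adherent:
                entry["adherent"].extend(adherent)
            if np.isfinite(pos_mean):
                entry["ratios"].append(
                    standardize_to_control(float(np.mean(pct)), pos_mean))
            entry["plates"].append(pid)

    out = []
    for sid, entry in rows.items():
        pct = np.asarray(entry["pct"], dtype=float)
        mean = float(pct.mean())
        sd = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
        out.append({
            "sample_id": sid,
            "n_rep": int(pct.size),
            "pct_input_rfu_mean": mean,
            "pct_input_rfu_sd": sd,
            "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
            "pct_adherent_mean": (float(np.mean(entry["adherent"]))
                                  if entry["adherent"] else np.nan),
            "standardized_coefficient": (float(np.mean(entry["ratios"]))
                                         if entry["ratios"] else np.nan),
            "plate_ids": ";".join(entry["plates"]),
            "flagged_over_100": bool(mean > 120.0),
        })
    return pd.DataFrame(out)


def fit_study_curves(curve_points: pd.DataFrame) -> dict[str, FourPLCurve]:
    """Fit one 4PL curve per plate from a standard-curve point table.

    ``curve_points`` has columns plate_id, sample_id, known_cells, rfu.
    Points with empty plate_id are pooled into a study-wide curve under the
    key ``""``.
    """
    curves: dict[str, FourPLCurve] = {}
    for pid, grp in curve_points.groupby("plate_id", sort=False):
        curves[str(pid)] = fit_four_pl(grp["known_cells"].to_numpy(),
                                       grp["rfu"].to_numpy())
    return curves


def write_phenotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
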