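"""Readers, writers and validators for plate-based adhesion-assay tables.

The canonical on-disk dialect is long/tidy CSV (RFC 4180, UTF-8, header row):
one well reading per row.  Four tables describe a study:

* **readings** — ``plate_id, well, sample_id, role, read_stage, rfu[, known_cells]``
* **layouts** — ``plate_id, well, sample_id, role``
* **standard curve points** — ``plate_id, sample_id, known_cells, rfu``
* **pair manifest** — ``pair_id, zygosity, sample_id_a, sample_id_b`` plus
  free covariate columns (age, sex, ethnicity, growth_class,
  transformation_time, ...)

Wells are addressed plate-reader style: rows A-H, columns 1-12, 1-based
(``A1`` ... ``H12``).  A missing ``rfu`` cell means the well is absent from
the study (it is dropped, never coerced to zero).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

ROLES = frozenset(
    {"test", "positive_control", "negative_control", "endothelial_only_blank",
     "standard_curve"}
)
READ_STAGES = frozenset({"pre_wash", "wash1", "wash2", "wash3"})

#: zygosity tokens accepted on input (case-insensitive); DZ is an alias for
#: SIB because full-sibling pairs are treated as dizygotic twins.
_ZYGOSITY_ALIASES = {"mz": "MZ", "sib": "SIB", "dz": "SIB"}

READINGS_COLUMNS = ["plate_id", "well", "sample_id", "role", "read_stage", "rfu"]
PAIRS_COLUMNS = ["pair_id", "zygosity", "sample_id_a", "sample_id_b"]
COVARIATE_COLUMNS = ["age", "sex", "ethnicity", "growth_class", "transformation_time"]


def _check_well(well: str) -> None:
    if not WELL_RE.match(str(well)):
        raise ValidationError(
            f"malformed well label {well!r}: expected rows A-H, columns 1-12"
        )


@dataclass(frozen=True)
class WellReading:
    """A single fluorescence measurement of one well at one read stage."""

    plate_id: str
    well: str
    sample_id: str
    role: str
    read_stage: str
    rfu: float
    known_cells: Optional[float] = None

    def __post_init__(self) -> None:
        _check_well(self.well)
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.read_stage not in READ_STAGES:
            raise ValidationError(f"unknown read_stage {self.read_stage!r}")
        if not (self.rfu >= 0):
            raise ValidationError(
                f"negative or non-finite rfu {self.rfu!r} in well "
                f"{self.plate_id}/{self.well}"
            )
        if (self.known_cells is not None) != (self.role == "standard_curve"):
            raise ValidationError(
                f"known_cells must be present iff role is standard_curve "
                f"(well {self.plate_id}/{self.well}, role {self.role!r})"
            )

    @property
    def key(self) -> tuple:
        return (self.plate_id, self.well, self.read_stage)


class PlateReadingSet:
    """All well readings for one study, in input order.

    Duplicate (plate, well, stage) keys are rejected at construction.
    """

    def __init__(self, readings: Iterable[WellReading]):
        self._readings = tuple(readings)
        seen: set[tuple] = set()
        for r in self._readings:
            if r.key in seen:
                raise ValidationError(
                    f"duplicate reading for plate {r.plate_id}, well {r.well}, "
                    f"stage {r.read_stage}"
                )
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self._readings)

    def __iter__(self):
        return iter(self._readings)

    def __eq__(self, other) -> bool:
        return isinstance(other, PlateReadingSet) and self._readings == other._readings

    @property
    def plate_ids(self) -> list[str]:
        out: list[str] = []
        for r in self._readings:
            if r.plate_id not in out:
                out.append(r.plate_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": r.plate_id,
                "well": r.well,
                "sample_id": r.sample_id,
                "role": r.role,
                "read_stage": r.read_stage,
                "rfu": r.rfu,
                "known_cells": r.known_cells,
            }
            for r in self._readings
        ]
        df = pd.DataFrame(rows, columns=READINGS_COLUMNS + ["known_cells"])
        return df

    def subset(self, *, plate_id=None, role=None, read_stage=None,
               sample_id=None) -> "PlateReadingSet":
        keep = []
        for r in self._readings:
            if plate_id is not None and r.plate_id != plate_id:
                continue
            if role is not None and r.role != role:
                continue
            if read_stage is not None and r.read_stage != read_stage:
                continue
            if sample_id is not None and r.sample_id != sample_id:
                continue
            keep.append(r)
        return PlateReadingSet(keep)

    def rfu_values(self, **kwargs) -> list[float]:
        return [r.rfu for r in self.subset(**kwargs)]


@dataclass(frozen=True)
class PlateLayout:
    """Map from wells of one plate to (sample_id, role)."""

    plate_id: str
    wells: Mapping[str, tuple[str, str]]
    replicates_per_sample: int = 8

    def __post_init__(self) -> None:
        for well, (sample, role) in self.wells.items():
            _check_well(well)
            if role not in ROLES:
                raise ValidationError(
                    f"unknown role {role!r} for well {self.plate_id}/{well}"
                )
        if self.replicates_per_sample < 1:
            raise ValidationError("replicates_per_sample must be positive")

    def samples_with_role(self, role: str) -> list[str]:
        out: list[str] = []
        for sample, r in self.wells.values():
            if r == role and sample not in out:
                out.append(sample)
        return out


@dataclass(frozen=True)
class PairRecord:
    """One MZ twin pair or full-sibling pair and its subject covariates."""

    pair_id: str
    zygosity: str  # "MZ" | "SIB"
    sample_id_a: str
    sample_id_b: str
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "SIB"):
            raise ValidationError(f"unknown zygosity {self.zygosity!r}")
        if self.sample_id_a == self.sample_id_b:
            raise ValidationError(
                f"pair {self.pair_id}: both members are {self.sample_id_a!r}"
            )

    @property
    def sample_ids(self) -> tuple[str, str]:
        return (self.sample_id_a, self.sample_id_b)


@dataclass
class ValidationReport:
    """Cross-table consistency report; collects every failure, never raises."""

    issues: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, kind: str, message: str, **context) -> None:
        self.issues.append({"kind": kind, "message": message, **context})

    def to_json(self, path=None) -> str:
        payload = json.dumps({"ok": self.ok, "issues": self.issues}, indent=2)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_plate_readings(path) -> PlateReadingSet:
    """Read the long-format readings CSV into a :class:`PlateReadingSet`.

    Rows with an empty ``rfu`` cell are treated as absent wells and dropped.
    Row order is preserved; duplicate (plate, well, stage) rows are rejected.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "sample_id": str},
                     float_precision="round_trip")
    _require_columns(df, READINGS_COLUMNS, path)
    has_known = "known_cells" in df.columns
    readings: list[WellReading] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if pd.isna(row.rfu):
            continue  # absent well, not zero
        rfu = float(row.rfu)
        if rfu < 0:
            raise ValidationError(f"{path}, line {i}: negative rfu {rfu}")
        known = None
        if has_known and not pd.isna(row.known_cells):
            known = float(row.known_cells)
        try:
            readings.append(
                WellReading(
                    plate_id=str(row.plate_id),
                    well=str(row.well),
                    sample_id=str(row.sample_id),
                    role=str(row.role),
                    read_stage=str(row.read_stage),
                    rfu=rfu,
                    known_cells=known,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    return PlateReadingSet(readings)


def write_plate_readings(readings: PlateReadingSet, path) -> None:
    df = readings.to_frame()
    # %.17g round-trips doubles exactly, keeping write(read(x)) == x
    df.to_csv(path, index=False, float_format="%.17g")


def read_plate_layouts(path, replicates_per_sample: int = 8) -> list[PlateLayout]:
    """Read the layout CSV (one row per assigned well) into per-plate layouts."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["plate_id", "well", "sample_id", "role"], path)
    layouts = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        wells = {}
        for row in grp.itertuples(index=False):
            if row.well in wells:
                raise ValidationError(
                    f"{path}: well {row.well} assigned twice on plate {plate_id}"
                )
            wells[row.well] = (row.sample_id, row.role)
        layouts.append(
            PlateLayout(plate_id=str(plate_id), wells=wells,
                        replicates_per_sample=replicates_per_sample)
        )
    return layouts


def write_plate_layouts(layouts: Sequence[PlateLayout], path) -> None:
    rows = []
    for layout in layouts:
        for well, (sample, role) in layout.wells.items():
            rows.append({"plate_id": layout.plate_id, "well": well,
                         "sample_id": sample, "role": role})
    pd.DataFrame(rows, columns=["plate_id", "well", "sample_id", "role"]).to_csv(
        path, index=False)


def read_standard_curve_points(path) -> pd.DataFrame:
    """Read standard-curve calibration points.

    Returns a DataFrame with columns ``plate_id, sample_id, known_cells, rfu``
    (``plate_id``/``sample_id`` optional in the file; filled with "" when
    absent so curves can still be grouped study-wide).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["known_cells", "rfu"], path)
    for col in ("plate_id", "sample_id"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].astype(str)
    if (df["rfu"] < 0).any():
        bad = int(df.index[df["rfu"] < 0][0]) + 2
        raise ValidationError(f"{path}, line {bad}: negative rfu")
    if (df["known_cells"] <= 0).any():
        bad = int(df.index[df["known_cells"] <= 0][0]) + 2
        raise ValidationError(f"{path}, line {bad}: known_cells must be positive")
    return df[["plate_id", "sample_id", "known_cells", "rfu"]]


def read_pair_manifest(path) -> list[PairRecord]:
    """Read the pair manifest CSV.

    Zygosity is parsed case-insensitively (``DZ`` is accepted as an alias for
    ``SIB``).  Missing covariate cells are recorded as absent, never imputed.
    """
    df = pd.read_csv(path, dtype={"pair_id": str, "sample_id_a": str,
                                  "sample_id_b": str})
    _require_columns(df, PAIRS_COLUMNS, path)
    if df.empty:
        logger.warning("pair manifest %s is empty", path)
        return []
    covariate_cols = [c for c in df.columns if c not in PAIRS_COLUMNS]
    pairs: list[PairRecord] = []
    seen_samples: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        token = str(row.zygosity).strip().lower()
        if token not in _ZYGOSITY_ALIASES:
            raise ValidationError(
                f"{path}, line {i}: unknown zygosity token {row.zygosity!r}"
            )
        for sid in (str(row.sample_id_a), str(row.sample_id_b)):
            if sid in seen_samples:
                raise ValidationError(
                    f"{path}, line {i}: sample {sid!r} already appears in pair "
                    f"{seen_samples[sid]!r}"
                )
        covs = {}
        for col in covariate_cols:
            val = getattr(row, col)
            if not pd.isna(val):
                covs[col] = val
        rec = PairRecord(
            pair_id=str(row.pair_id),
            zygosity=_ZYGOSITY_ALIASES[token],
            sample_id_a=str(row.sample_id_a),
            sample_id_b=str(row.sample_id_b),
            covariates=covs,
        )
        seen_samples[rec.sample_id_a] = rec.pair_id
        seen_samples[rec.sample_id_b] = rec.pair_id
        pairs.append(rec)
    return pairs


def write_pair_manifest(pairs: Sequence[PairRecord], path) -> None:
    cov_cols: list[str] = []
    for p in pairs:
        for c in p.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    rows = []
    for p in pairs:
        row = {"pair_id": p.pair_id, "zygosity": p.zygosity,
               "sample_id_a": p.sample_id_a, "sample_id_b": p.sample_id_b}
        for c in cov_cols:
            row[c] = p.covariates.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=PAIRS_COLUMNS + cov_cols).to_csv(path, index=False)


def read_plate_matrix(path, *, plate_id: str, read_stage: str,
                      layout: PlateLayout) -> PlateReadingSet:
    """Convenience shim: import an 8x12 matrix CSV (rows A-H x columns 1-12).

    The matrix carries RFU only; sample identity and role come from
    ``layout``.  Empty cells are absent wells.
    """
    df = pd.read_csv(path, index_col=0)
    readings = []
    for row_label, row in df.iterrows():
        for col_label, value in row.items():
            if pd.isna(value):
                continue
            well = f"{row_label}{int(col_label)}"
            if well not in layout.wells:
                continue
            sample, role = layout.wells[well]
            readings.append(
                WellReading(plate_id=plate_id, well=well, sample_id=sample,
                            role=role, read_stage=read_stage, rfu=float(value))
            )
    return PlateReadingSet(readings)


# ---------------------------------------------------------------------------
# cross-table validation


def validate_study(readings: PlateReadingSet, layouts: Sequence[PlateLayout],
                   pairs: Sequence[PairRecord]) -> ValidationReport:
    """Cross-check readings, layouts and the pair manifest.

    Flags (without raising): plates lacking positive/negative control wells,
    and paired samples that cannot be quantified because they have no test
    well with both a pre_wash and a wash3 reading.
    """
    report = ValidationReport()

    for layout in layouts:
        for role in ("positive_control", "negative_control"):
            n = sum(1 for _, r in layout.wells.values() if r == role)
            if n == 0:
                report.add("missing_controls",
                           f"plate {layout.plate_id} has no {role} wells",
                           plate_id=layout.plate_id, role=role)

    # stages observed per (sample, plate, well) among test wells
    stages: dict[str, dict[tuple, set]] = {}
    for r in readings:
        if r.role != "test":
            continue
        stages.setdefault(r.sample_id, {}).setdefault(
            (r.plate_id, r.well), set()).add(r.read_stage)

    paired_samples = [sid for p in pairs for sid in p.sample_ids]
    for sid in paired_samples:
        wells = stages.get(sid, {})
        quantifiable = any({"pre_wash", "wash3"} <= s for s in wells.values())
        if not quantifiable:
            report.add("unquantifiable_sample",
                       f"sample {sid} has no test well with both pre_wash and "
                       f"wash3 readings", sample_id=sid)
    return report
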