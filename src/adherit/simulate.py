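"""Synthetic twin-study generator.

Emulates the study design end to end so every pipeline stage is testable
without external data: 23 monozygotic and 23 full-sibling pairs of
lymphoblastoid lines, each assayed in 8 technical replicate wells on
96-well plates carrying Trisomy-21-like positive controls (~35 % adhesion),
Ramos-like negative controls (~5 %), and per-plate 4PL standard-curve wells.

Pair phenotypes follow the standard additive (ACE-style) decomposition on
the % input RFU scale:

    y = mu + sigma * (sqrt(h2) A + sqrt(c2) C + sqrt(1 - h2 - c2) E)

with the additive component A shared fully within MZ pairs and with
correlation 1/2 within sibling pairs, the common environment C shared
within every pair, and E independent.  Implied intra-pair correlations are
r_MZ = h2 + c2 and r_SIB = h2/2 + c2, so the Falconer estimator targets h2
by construction.

Replicate noise is multiplicative log-normal at a fixed CV (fluorescence
noise scales with signal); it is applied to the post-wash read, so the
per-well % input RFU carries exactly that CV.  Defaults reproduce the
reported assay operating point: phenotype mean 40.25 %, sd 10.37, replicate
CV 8.68 %.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .heritability import PhenotypePair
from .plate_io import (PairRecord, PlateLayout, PlateReadingSet, WellReading,
                       write_pair_manifest, write_plate_layouts,
                       write_plate_readings)
from .quantify import four_pl

POSITIVE_CONTROL_ID = "TRISOMY21"
NEGATIVE_CONTROL_ID = "RAMOS"

#: cell loads for the per-plate standard-curve wells (cells/well)
STANDARD_CURVE_LOADS = (625.0, 1250.0, 2500.0, 5000.0, 10_000.0, 20_000.0,
                        40_000.0, 80_000.0)
#: multiplicative CV of the calibration wells (pipetting precision)
STANDARD_CURVE_CV = 2.0

_ETHNICITIES = ("White", "Black")
_SEXES = ("F", "M")


@dataclass(frozen=True)
class GenerativeConfig:
    """Study-design parameters of the synthetic cohort and plates."""

    n_mz_pairs: int = 23
    n_sib_pairs: int = 23
    h2: float = 0.6966          # additive-genetic variance fraction
    c2: float = 0.10            # shared-environment variance fraction
    phenotype_mean: float = 40.25   # % input RFU
    phenotype_sd: float = 10.37     # %
    replicate_cv: float = 8.68      # % technical replicate CV
    pos_control_mean: float = 35.0  # % adhesion, Trisomy-21-like line
    neg_control_mean: float = 5.0   # % adhesion, Ramos-like line
    replicates_per_sample: int = 8
    loaded_cells: float = 50_000.0  # cells added per well
    # 4PL standard curve: zero-cell asymptote a, saturation d (RFU),
    # inflection c (cells/well), slope b
    curve_a: float = 150.0
    curve_d: float = 60_000.0
    curve_c: float = 20_000.0
    curve_b: float = 1.5
    plate_gain_cv: float = 0.0      # % CV of per-plate gain batch effect
    inject_confounder: Optional[str] = None
    confounder_beta: float = 0.0    # phenotype-% shift per sd of covariate
    seed: int = 0

    def __post_init__(self):
        if self.h2 < 0 or self.c2 < 0 or self.h2 + self.c2 > 1:
            raise ConfigError(
                f"need h2 >= 0, c2 >= 0, h2 + c2 <= 1; got h2={self.h2}, "
                f"c2={self.c2}"
            )
        for name in ("phenotype_sd", "replicate_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def r_mz_implied(self) -> float:
        return self.h2 + self.c2

    @property
    def r_sib_implied(self) -> float:
        return self.h2 / 2.0 + self.c2


@dataclass
class SimulatedCohort:
    """Pairs, per-sample true phenotypes and generation bookkeeping."""

    pair_records: list
    phenotypes: dict            # sample_id -> true % input RFU (post-clip)
    clip_fraction: float
    config: GenerativeConfig

    @property
    def phenotype_pairs(self) -> list[PhenotypePair]:
        return [PhenotypePair(pair_id=p.pair_id, zygosity=p.zygosity,
                              y_a=self.phenotypes[p.sample_id_a],
                              y_b=self.phenotypes[p.sample_id_b])
                for p in self.pair_records]

    def group_matrix(self, zygosity: str) -> np.ndarray:
        """(n, 2) phenotype matrix for one zygosity group."""
        return np.array([[self.phenotypes[p.sample_id_a],
                          self.phenotypes[p.sample_id_b]]
                         for p in self.pair_records
                         if p.zygosity == zygosity], dtype=float)


def _lognormal_factor(rng: np.random.Generator, cv_percent: float,
                      size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise at the given CV."""
    if cv_percent == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p((cv_percent / 100.0) ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def _draw_covariates(rng: np.random.Generator, n: int) -> list[dict]:
    ages = rng.integers(12, 61, size=n)
    sexes = rng.integers(0, 2, size=n)
    eth = rng.random(size=n) > 0.7
    growth = rng.random(size=n) < 0.5
    ttime = rng.integers(20, 61, size=n)
    return [{
        "age": int(ages[i]),
        "sex": _SEXES[int(sexes[i])],
        "ethnicity": _ETHNICITIES[int(eth[i])],
        "growth_class": "fast" if growth[i] else "slow",
        "transformation_time": int(ttime[i]),
    } for i in range(n)]


def simulate_pair_phenotypes(config: GenerativeConfig,
                             rng: Optional[np.random.Generator] = None
                             ) -> SimulatedCohort:
    """Draw pair phenotypes from the additive model plus pair covariates.

    Phenotypes are clipped to (1, 99) % before plate simulation; at the
    default operating point the clip rate is far below 0.1 %, so the genetic
    signal is not distorted.  Covariates are independent of phenotype unless
    ``inject_confounder`` names one.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h2, c2 = config.h2, config.c2
    e2 = 1.0 - h2 - c2

    records, phen = [], {}
    n_clipped = n_total = 0
    for zyg, n_pairs in (("MZ", config.n_mz_pairs), ("SIB", config.n_sib_pairs)):
        if n_pairs == 0:
            continue
        if zyg == "MZ":
            a = np.repeat(rng.standard_normal((n_pairs, 1)), 2, axis=1)
        else:
            shared = rng.standard_normal((n_pairs, 1))
            a = np.sqrt(0.5) * shared \
                + np.sqrt(0.5) * rng.standard_normal((n_pairs, 2))
        c_shared = rng.standard_normal((n_pairs, 1))
        e = rng.standard_normal((n_pairs, 2))
        covs = _draw_covariates(rng, n_pairs)
        shift = np.zeros(n_pairs)
        if config.inject_confounder:
            vals = [c[config.inject_confounder] for c in covs]
            # binary/categorical covariates: second level codes as 1
            num = np.array([float(v in ("M", "fast", _ETHNICITIES[1]))
                            if isinstance(v, str) else float(v)
                            for v in vals])
            shift = config.confounder_beta * num
        y = (config.phenotype_mean
             + config.phenotype_sd * (np.sqrt(h2) * a + np.sqrt(c2) * c_shared
                                      + np.sqrt(e2) * e)
             + shift[:, None])
        n_total += y.size
        clipped = (y <= 1.0) | (y >= 99.0)
        n_clipped += int(clipped.sum())
        y = np.clip(y, 1.0, 99.0)
        for i in range(n_pairs):
            pair_id = f"{zyg}{i + 1:03d}"
            sid_a, sid_b = f"{pair_id}A", f"{pair_id}B"
            records.append(PairRecord(pair_id=pair_id, zygosity=zyg,
                                      sample_id_a=sid_a, sample_id_b=sid_b,
                                      covariates=covs[i]))
            phen[sid_a], phen[sid_b] = float(y[i, 0]), float(y[i, 1])
    return SimulatedCohort(pair_records=records, phenotypes=phen,
                           clip_fraction=n_clipped / max(n_total, 1),
                           config=config)


def _paginate(sample_ids: Sequence[str], per_plate: int) -> list[list[str]]:
    return [list(sample_ids[i:i + per_plate])
            for i in range(0, len(sample_ids), per_plate)]


def simulate_plate_readings(phenotypes: Mapping[str, float],
                            config: GenerativeConfig,
                            rng: Optional[np.random.Generator] = None,
                            gains: Optional[Mapping[str, float] | float] = None
                            ) -> tuple[PlateReadingSet, list[PlateLayout],
                                       pd.DataFrame]:
    """Lay samples out on 96-well plates and synthesize well readings.

    Per plate: up to 8 test samples x 8 replicate wells plus 8
    positive-control wells (rows A-F), 8 negative-control wells (row G),
    and 8 standard-curve wells (row H) at known cell loads.  Overflowing
    samples paginate onto additional plates.  Each test/control well gets a noiseless pre-wash
    read at the loaded-cell fluorescence and a post-wash read at the
    phenotype fraction of it, with mean-one log-normal replicate noise; an
    optional per-plate gain multiplies every read on the plate.

    Returns (readings, layouts, standard-curve point table).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    nrep = config.replicates_per_sample
    # rows A-F hold test wells plus 8 positive-control wells; controls get
    # the same 8-replicate depth as the samples so per-plate Z' is stable
    per_plate = (6 * 12 - 8) // nrep
    pages = _paginate(list(phenotypes), per_plate)

    def plate_gain(pid: str) -> float:
        if gains is None:
            if config.plate_gain_cv == 0:
                return 1.0
            return float(_lognormal_factor(rng, config.plate_gain_cv, None))
        if isinstance(gains, (int, float)):
            return float(gains)
        return float(gains.get(pid, 1.0))

    pre_rfu_clean = float(four_pl(config.loaded_cells, config.curve_a,
                                  config.curve_d, config.curve_c,
                                  config.curve_b))

    readings: list[WellReading] = []
    layouts: list[PlateLayout] = []
    curve_rows: list[dict] = []
    for page_no, samples in enumerate(pages, start=1):
        pid = f"P{page_no:02d}"
        g = plate_gain(pid)
        wells: dict[str, tuple[str, str]] = {}

        def add_sample_wells(sid: str, role: str, pct: float,
                             well_list: Sequence[str]) -> None:
            noise = _lognormal_factor(rng, config.replicate_cv,
                                      len(well_list))
            for w, nz in zip(well_list, noise):
                wells[w] = (sid, role)
                pre = pre_rfu_clean * g
                post = (pct / 100.0) * pre_rfu_clean * nz * g
                readings.append(WellReading(pid, w, sid, role, "pre_wash", pre))
                readings.append(WellReading(pid, w, sid, role, "wash3", post))

        grid_af = [f"{row}{col}" for row in "ABCDEF" for col in range(1, 13)]
        for k, sid in enumerate(samples):
            add_sample_wells(sid, "test", phenotypes[sid],
                             grid_af[k * nrep:(k + 1) * nrep])
        add_sample_wells(POSITIVE_CONTROL_ID, "positive_control",
                         config.pos_control_mean, grid_af[-8:])
        add_sample_wells(NEGATIVE_CONTROL_ID, "negative_control",
                         config.neg_control_mean,
                         [f"G{c}" for c in range(1, 9)])

        std_noise = _lognormal_factor(rng, STANDARD_CURVE_CV,
                                      len(STANDARD_CURVE_LOADS))
        for j, (load, nz) in enumerate(zip(STANDARD_CURVE_LOADS, std_noise),
                                       start=1):
            w = f"H{j}"
            wells[w] = ("STD", "standard_curve")
            rfu = float(four_pl(load, config.curve_a, config.curve_d,
                                config.curve_c, config.curve_b)) * nz * g
            readings.append(WellReading(pid, w, "STD", "standard_curve",
                                        "pre_wash", rfu, known_cells=load))
            curve_rows.append({"plate_id": pid, "sample_id": "STD",
                               "known_cells": load, "rfu": rfu})

        layouts.append(PlateLayout(plate_id=pid, wells=wells,
                                   replicates_per_sample=nrep))

    curve_points = pd.DataFrame(
        curve_rows, columns=["plate_id", "sample_id", "known_cells", "rfu"])
    return PlateReadingSet(readings), layouts, curve_points


def make_fixture_study(config: GenerativeConfig, out_dir) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Files: readings.csv, layouts.csv, standard_curve.csv, pairs.csv (the four
    canonical tables), ground_truth.json (generative truth for assertions)
    and manifest.json (files + echoed parameters).  Byte-identical for equal
    seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    cohort = simulate_pair_phenotypes(config, rng)
    readings, layouts, curve_points = simulate_plate_readings(
        cohort.phenotypes, config, rng)

    files = {
        "readings": "readings.csv",
        "layouts": "layouts.csv",
        "standard_curve": "standard_curve.csv",
        "pairs": "pairs.csv",
        "ground_truth": "ground_truth.json",
    }
    write_plate_readings(readings, out / files["readings"])
    write_plate_layouts(layouts, out / files["layouts"])
    curve_points.to_csv(out / files["standard_curve"], index=False)
    write_pair_manifest(cohort.pair_records, out / files["pairs"])

    truth = {
        "h2": config.h2, "c2": config.c2,
        "r_mz_implied": config.r_mz_implied,
        "r_sib_implied": config.r_sib_implied,
        "seed": config.seed,
        "clip_fraction": cohort.clip_fraction,
        "phenotypes": cohort.phenotypes,
    }
    (out / files["ground_truth"]).write_text(json.dumps(truth, indent=2,
                                                        sort_keys=True),
                                             encoding="utf-8")
    manifest = {"files": files, "config": asdict(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True),
                                       encoding="utf-8")
    return manifest
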