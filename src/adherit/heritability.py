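"""Twin-design heritability of a quantitative cellular phenotype.

The design compares monozygotic (MZ) twin pairs, who share all additive
genetic variation, with full-sibling pairs, who share half of it on average
and are treated as dizygotic twins.  Intra-pair resemblance is measured by
the one-way random-effects intraclass correlation (ICC) for exchangeable
pair members,

    ICC = (MS_between - MS_within) / (MS_between + MS_within),

with the double-entry Pearson correlation available as an alternative
estimator (the two agree to O(1/n)).  Narrow-sense heritability follows
Falconer's formula

    h^2 = 2 (r_MZ - r_DZ),

and its significance is assessed against a permutation null: all individual
phenotypes are pooled and randomly re-dealt into pseudo-pairs of the
original group sizes, h^2 is recomputed, and the empirical p-value uses the
add-one estimator p = (1 + #{h2_null >= h2_obs}) / (1 + n_perm), which is
never zero.

The model object follows the build-from-data / fit / results convention:

>>> model = TwinHeritabilityModel.from_pairs(pairs)
>>> res = model.fit(n_perm=10_000, seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (ConfigError, DegenerateDataError,
                         InsufficientDataError, ValidationError)
from .plate_io import PairRecord

__all__ = [
    "PhenotypePair", "TwinHeritabilityModel", "HeritabilityResults",
    "intraclass_correlation", "pearson_double_entry", "falconer_h2",
    "permutation_pvalue", "PermutationNull", "confounder_screen",
    "variance_equality", "VarianceEqualityResult", "run_heritability_analysis",
]

ESTIMATORS = ("icc_anova", "pearson_double_entry")


@dataclass(frozen=True)
class PhenotypePair:
    """Phenotypes of both members of one pair, on a common scale."""

    pair_id: str
    zygosity: str  # "MZ" | "SIB"
    y_a: float
    y_b: float

    def __post_init__(self):
        if self.zygosity not in ("MZ", "SIB"):
            raise ValidationError(f"unknown zygosity {self.zygosity!r}")
        if not (np.isfinite(self.y_a) and np.isfinite(self.y_b)):
            raise ValidationError(f"pair {self.pair_id}: non-finite phenotype")


def _as_matrix(pairs) -> np.ndarray:
    """Coerce pairs (PhenotypePair list or (n,2) array-like) to an (n,2) array."""
    if len(pairs) and isinstance(pairs[0], PhenotypePair):
        arr = np.array([[p.y_a, p.y_b] for p in pairs], dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of phenotypes")
    return arr


def _icc_components(arr3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MS_between and MS_within for stacked pair matrices of shape (..., n, 2)."""
    n = arr3.shape[-2]
    pair_means = arr3.mean(axis=-1)                       # (..., n)
    grand = pair_means.mean(axis=-1, keepdims=True)       # (..., 1)
    ssb = 2.0 * ((pair_means - grand) ** 2).sum(axis=-1)
    ssw = 0.5 * ((arr3[..., 0] - arr3[..., 1]) ** 2).sum(axis=-1)
    return ssb / (n - 1), ssw / n


def intraclass_correlation(pairs) -> float:
    """One-way random-effects ANOVA ICC for exchangeable pair members (k=2).

    (MS_between - MS_within)/(MS_between + MS_within); bounded in [-1, 1] and
    invariant to the order of members within each pair.
    """
    arr = _as_matrix(pairs)
    if arr.shape[0] < 3:
        raise InsufficientDataError(
            f"ICC needs >=3 pairs, got {arr.shape[0]}"
        )
    msb, msw = _icc_components(arr)
    total = msb + msw
    if total == 0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    return float((msb - msw) / total)


def pearson_double_entry(pairs) -> float:
    """Pearson correlation over the double-entered pair list.

    Each pair (a, b) enters twice, as (a, b) and (b, a), making the estimator
    symmetric in pair members.
    """
    arr = _as_matrix(pairs)
    if arr.shape[0] < 3:
        raise InsufficientDataError(
            f"double-entry correlation needs >=3 pairs, got {arr.shape[0]}"
        )
    g = arr.mean()
    dev = arr - g
    denom = (dev ** 2).sum()
    if denom == 0:
        raise DegenerateDataError("correlation undefined: zero variance")
    cov = 2.0 * (dev[:, 0] * dev[:, 1]).sum()
    return float(cov / denom)


def _estimate(arr: np.ndarray, estimator: str) -> float:
    if estimator == "icc_anova":
        return intraclass_correlation(arr)
    if estimator == "pearson_double_entry":
        return pearson_double_entry(arr)
    raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")


def falconer_h2(r_mz: float, r_sib: float, truncate: bool = False) -> float:
    """Falconer's estimate h^2 = 2 (r_MZ - r_DZ).

    The raw value is returned even outside [0, 1]; ``truncate=True`` clips.
    """
    for name, r in (("r_mz", r_mz), ("r_sib", r_sib)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [-1, 1], got {r}")
    h2 = 2.0 * (r_mz - r_sib)
    if truncate:
        h2 = min(max(h2, 0.0), 1.0)
    return float(h2)


# ---------------------------------------------------------------------------
# permutation inference


@dataclass(frozen=True)
class PermutationNull:
    """Permutation null distribution of h^2 and the empirical p-value."""

    p_value: float
    n_perm: int
    h2_observed: float
    null_mean: float
    null_sd: float
    null_quantiles: Mapping[str, float]
    scheme: str

    def to_dict(self) -> dict:
        return {"p_value": self.p_value, "n_perm": self.n_perm,
                "h2_observed": self.h2_observed, "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "null_quantiles": dict(self.null_quantiles),
                "scheme": self.scheme}


def _vectorized_estimates(stack: np.ndarray, estimator: str) -> np.ndarray:
    """Estimator applied along the first axis of a (B, n, 2) stack."""
    msb, msw = _icc_components(stack)
    if estimator == "icc_anova":
        total = msb + msw
        with np.errstate(invalid="ignore", divide="ignore"):
            return (msb - msw) / total
    # double-entry Pearson, closed form
    g = stack.mean(axis=(-1, -2), keepdims=True)
    dev = stack - g
    denom = (dev ** 2).sum(axis=(-1, -2))
    cov = 2.0 * (dev[..., 0] * dev[..., 1]).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / denom


def permutation_pvalue(mz_pairs, sib_pairs, n_perm: int = 10_000,
                       seed: Optional[int] = None,
                       estimator: str = "icc_anova",
                       scheme: str = "pool_individuals",
                       rng: Optional[np.random.Generator] = None
                       ) -> PermutationNull:
    """Empirical p-value for h^2 against a permutation null.

    ``pool_individuals`` (default): all 2*N_MZ + 2*N_SIB phenotypes are
    pooled and re-dealt into pseudo-pairs preserving the group sizes, which
    breaks both pairing and zygosity structure.  ``pair_labels``: zygosity
    labels are permuted across intact pairs, preserving pairing.

    p = (1 + #{h2_null >= h2_obs}) / (1 + n_perm), never zero.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >=1, got {n_perm}")
    mz = _as_matrix(mz_pairs)
    sib = _as_matrix(sib_pairs)
    n_mz, n_sib = mz.shape[0], sib.shape[0]
    h2_obs = falconer_h2(_estimate(mz, estimator), _estimate(sib, estimator))

    if rng is None:
        rng = np.random.default_rng(seed)

    if scheme == "pool_individuals":
        pooled = np.concatenate([mz.ravel(), sib.ravel()])
        tiled = np.broadcast_to(pooled, (n_perm, pooled.size))
        shuffled = rng.permuted(tiled, axis=1)
        mz_null = shuffled[:, : 2 * n_mz].reshape(n_perm, n_mz, 2)
        sib_null = shuffled[:, 2 * n_mz:].reshape(n_perm, n_sib, 2)
    elif scheme == "pair_labels":
        allp = np.concatenate([mz, sib], axis=0)
        idx = np.broadcast_to(np.arange(allp.shape[0]),
                              (n_perm, allp.shape[0]))
        idx = rng.permuted(idx, axis=1)
        mz_null = allp[idx[:, :n_mz]]
        sib_null = allp[idx[:, n_mz:]]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    null = 2.0 * (_vectorized_estimates(mz_null, estimator)
                  - _vectorized_estimates(sib_null, estimator))
    if np.isnan(null).any():
        raise DegenerateDataError(
            "estimator degenerate on permuted data (zero variance)"
        )
    p = (1.0 + float(np.sum(null >= h2_obs))) / (1.0 + n_perm)
    qs = np.quantile(null, [0.025, 0.25, 0.5, 0.75, 0.975])
    return PermutationNull(
        p_value=p, n_perm=n_perm, h2_observed=h2_obs,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        null_quantiles={"q2.5": float(qs[0]), "q25": float(qs[1]),
                        "q50": float(qs[2]), "q75": float(qs[3]),
                        "q97.5": float(qs[4])},
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# confounder screening


def confounder_screen(samples: pd.DataFrame, phenotype_col: str = "phenotype",
                      continuous: Sequence[str] = ("age", "transformation_time"),
                      binary: Sequence[str] = ("sex", "growth_class"),
                      categorical: Sequence[str] = ("ethnicity",)
                      ) -> pd.DataFrame:
    """Screen per-sample covariates for association with the phenotype.

    Continuous covariates: Pearson r with two-sided p.  Binary: two-sample
    t-test.  Multi-level categorical: one-way ANOVA.  Covariates constant
    across samples (or with <3 usable samples) are flagged not-testable.
    Unadjusted p-values are reported alongside a Bonferroni column.
    """
    rows = []
    plan = ([(c, "pearson") for c in continuous]
            + [(c, "ttest") for c in binary]
            + [(c, "anova") for c in categorical])
    for cov, kind in plan:
        if cov not in samples.columns:
            continue
        sub = samples[[phenotype_col, cov]].dropna()
        n = len(sub)
        row = {"covariate": cov, "kind": kind, "n": n, "statistic": np.nan,
               "p_value": np.nan, "testable": False, "note": ""}
        if n < 3:
            row["note"] = "fewer than 3 samples with covariate"
        elif sub[cov].nunique() < 2:
            row["note"] = "covariate constant across samples"
        elif kind == "pearson":
            r, p = stats.pearsonr(sub[cov].astype(float),
                                  sub[phenotype_col].astype(float))
            row.update(statistic=float(r), p_value=float(p), testable=True)
        elif kind == "ttest":
            levels = sub[cov].unique()
            if len(levels) != 2:
                row["note"] = f"expected 2 levels, got {len(levels)}"
            else:
                g0 = sub.loc[sub[cov] == levels[0], phenotype_col].astype(float)
                g1 = sub.loc[sub[cov] == levels[1], phenotype_col].astype(float)
                if min(len(g0), len(g1)) < 2:
                    row["note"] = "a level has <2 samples"
                else:
                    t, p = stats.ttest_ind(g0, g1)
                    row.update(statistic=float(t), p_value=float(p),
                               testable=True)
        else:  # anova
            groups = [grp[phenotype_col].astype(float).to_numpy()
                      for _, grp in sub.groupby(cov) if len(grp) >= 2]
            if len(groups) < 2:
                row["note"] = "fewer than 2 levels with >=2 samples"
            else:
                f, p = stats.f_oneway(*groups)
                row.update(statistic=float(f), p_value=float(p), testable=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        m = int(out["testable"].sum())
        out["p_bonferroni"] = np.where(
            out["testable"], np.minimum(out["p_value"] * max(m, 1), 1.0), np.nan)
    return out


@dataclass(frozen=True)
class VarianceEqualityResult:
    p_value: Optional[float]
    f_statistic: Optional[float]
    pairwise: Optional[pd.DataFrame] = None
    note: str = ""


def variance_equality(groups: Mapping[str, Sequence[float]]
                      ) -> VarianceEqualityResult:
    """Two-sided variance-ratio F-test between phenotype groups.

    The larger sample variance goes in the numerator and the one-tailed
    probability is doubled (capped at 1).  With more than two groups, all
    pairwise tests are run and Bonferroni-adjusted, flagged in the note.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise InsufficientDataError("variance test needs >=2 groups")
    for k, a in arrays.items():
        if a.size < 2:
            raise InsufficientDataError(f"group {k!r} has <2 values")
        if a.std(ddof=1) == 0:
            raise DegenerateDataError(f"group {k!r} has zero variance")

    def _ftest(x, y):
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx >= vy:
            f, dfn, dfd = vx / vy, x.size - 1, y.size - 1
        else:
            f, dfn, dfd = vy / vx, y.size - 1, x.size - 1
        p = min(2.0 * stats.f.sf(f, dfn, dfd), 1.0)
        return float(f), float(p)

    keys = list(arrays)
    if len(keys) == 2:
        f, p = _ftest(arrays[keys[0]], arrays[keys[1]])
        return VarianceEqualityResult(p_value=p, f_statistic=f)
    rows = []
    m = len(keys) * (len(keys) - 1) // 2
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            f, p = _ftest(arrays[keys[i]], arrays[keys[j]])
            rows.append({"group_a": keys[i], "group_b": keys[j],
                         "f_statistic": f, "p_value": p,
                         "p_bonferroni": min(p * m, 1.0)})
    table = pd.DataFrame(rows)
    return VarianceEqualityResult(
        p_value=float(table["p_bonferroni"].min()),
        f_statistic=None, pairwise=table,
        note=f">2 groups: {m} pairwise F-tests, Bonferroni-adjusted minimum "
             f"p reported")


# ---------------------------------------------------------------------------
# model / results objects


class TwinHeritabilityModel:
    """Falconer twin/sibling heritability model for one phenotype.

    Built from phenotype pairs (or a tidy DataFrame); ``fit`` estimates
    intra-pair correlations per zygosity group, Falconer h^2 and the
    permutation p-value, returning a :class:`HeritabilityResults`.
    """

    def __init__(self, pairs: Sequence[PhenotypePair]):
        self.pairs = list(pairs)
        self.mz = _as_matrix([p for p in self.pairs if p.zygosity == "MZ"]) \
            if any(p.zygosity == "MZ" for p in self.pairs) else np.empty((0, 2))
        self.sib = _as_matrix([p for p in self.pairs if p.zygosity == "SIB"]) \
            if any(p.zygosity == "SIB" for p in self.pairs) else np.empty((0, 2))
        if self.mz.shape[0] < 2 or self.sib.shape[0] < 2:
            raise InsufficientDataError(
                f"need >=2 pairs in each zygosity group, got "
                f"{self.mz.shape[0]} MZ and {self.sib.shape[0]} SIB"
            )

    @classmethod
    def from_pairs(cls, pairs: Sequence[PhenotypePair]) -> "TwinHeritabilityModel":
        return cls(pairs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pair_id: str = "pair_id",
                       zygosity: str = "zygosity", y_a: str = "y_a",
                       y_b: str = "y_b") -> "TwinHeritabilityModel":
        pairs = [PhenotypePair(pair_id=str(r[pair_id]),
                               zygosity=str(r[zygosity]).upper(),
                               y_a=float(r[y_a]), y_b=float(r[y_b]))
                 for _, r in df.iterrows()]
        return cls(pairs)

    @classmethod
    def from_phenotype_table(cls, phenotypes: Mapping[str, float],
                             pair_records: Sequence[PairRecord]
                             ) -> "TwinHeritabilityModel":
        """Join per-sample phenotype values onto a pair manifest."""
        missing = [sid for p in pair_records for sid in p.sample_ids
                   if sid not in phenotypes]
        if missing:
            raise ValidationError(
                f"{len(missing)} paired sample(s) lack phenotypes: "
                + ", ".join(sorted(missing)[:10])
                + ("..." if len(missing) > 10 else "")
            )
        pairs = [PhenotypePair(pair_id=p.pair_id, zygosity=p.zygosity,
                               y_a=float(phenotypes[p.sample_id_a]),
                               y_b=float(phenotypes[p.sample_id_b]))
                 for p in pair_records]
        return cls(pairs)

    def fit(self, estimator: str = "icc_anova", n_perm: int = 10_000,
            seed: Optional[int] = None, scheme: str = "pool_individuals",
            truncate_h2: bool = False) -> "HeritabilityResults":
        if estimator not in ESTIMATORS:
            raise ConfigError(
                f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
        r_mz = _estimate(self.mz, estimator)
        r_sib = _estimate(self.sib, estimator)
        h2_raw = falconer_h2(r_mz, r_sib)
        null = permutation_pvalue(self.mz, self.sib, n_perm=n_perm, seed=seed,
                                  estimator=estimator, scheme=scheme)
        return HeritabilityResults(
            model=self, r_mz=r_mz, r_sib=r_sib,
            h2=falconer_h2(r_mz, r_sib, truncate=truncate_h2),
            h2_raw=h2_raw, h2_out_of_range=not (0.0 <= h2_raw <= 1.0),
            p_empirical=null.p_value, n_perm=n_perm, null=null,
            estimator_used=estimator, seed=seed, scheme=scheme,
            n_mz=self.mz.shape[0], n_sib=self.sib.shape[0],
        )


@dataclass
class HeritabilityResults:
    """Fitted twin-model estimates, permutation null and provenance."""

    model: TwinHeritabilityModel
    r_mz: float
    r_sib: float
    h2: float
    h2_raw: float
    h2_out_of_range: bool
    p_empirical: float
    n_perm: int
    null: PermutationNull
    estimator_used: str
    seed: Optional[int]
    scheme: str
    n_mz: int
    n_sib: int
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r_mz": self.r_mz, "r_sib": self.r_sib, "h2": self.h2,
            "h2_raw": self.h2_raw, "h2_percent": 100.0 * self.h2,
            "h2_out_of_range": self.h2_out_of_range,
            "p_empirical": self.p_empirical, "n_perm": self.n_perm,
            "null": self.null.to_dict(), "estimator": self.estimator_used,
            "seed": self.seed, "scheme": self.scheme,
            "n_mz_pairs": self.n_mz, "n_sib_pairs": self.n_sib,
            "settings": self.settings,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    def summary(self) -> str:
        lines = [
            "Twin heritability of leukocyte-endothelial adhesion",
            "=" * 55,
            f"Pairs:              {self.n_mz} MZ, {self.n_sib} sibling",
            f"Estimator:          {self.estimator_used}",
            f"r_MZ:               {self.r_mz:8.4f}",
            f"r_SIB:              {self.r_sib:8.4f}",
            f"h2 = 2(r_MZ-r_SIB): {self.h2:8.4f}  ({100 * self.h2:.2f}%)"
            + ("  [outside [0,1]]" if self.h2_out_of_range else ""),
            f"Permutation p:      {self.p_empirical:8.4g}  "
            f"({self.n_perm} permutations, scheme={self.scheme}, "
            f"seed={self.seed})",
            f"Null h2:            mean {self.null.null_mean:.4f}, "
            f"sd {self.null.null_sd:.4f}, "
            f"95% [{self.null.null_quantiles['q2.5']:.3f}, "
            f"{self.null.null_quantiles['q97.5']:.3f}]",
        ]
        return "\n".join(lines)

    def plot_pairs(self, ax=None):
        """Scatter of member-A vs member-B phenotypes, MZ vs sibling pairs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mz, sib = self.model.mz, self.model.sib
        ax.scatter(mz[:, 0], mz[:, 1], label=f"MZ (r={self.r_mz:.2f})",
                   marker="o")
        ax.scatter(sib[:, 0], sib[:, 1], label=f"SIB (r={self.r_sib:.2f})",
                   marker="s")
        ax.set_xlabel("member A phenotype")
        ax.set_ylabel("member B phenotype")
        ax.legend()
        return ax


def run_heritability_analysis(phenotypes: Mapping[str, float],
                              pair_records: Sequence[PairRecord],
                              estimator: str = "icc_anova",
                              n_perm: int = 10_000,
                              seed: Optional[int] = None,
                              scheme: str = "pool_individuals",
                              truncate_h2: bool = False,
                              settings: Optional[dict] = None
                              ) -> HeritabilityResults:
    """Join phenotypes to the pair manifest, fit, and stamp provenance."""
    model = TwinHeritabilityModel.from_phenotype_table(phenotypes, pair_records)
    res = model.fit(estimator=estimator, n_perm=n_perm, seed=seed,
                    scheme=scheme, truncate_h2=truncate_h2)
    cfg = dict(settings or {})
    cfg.update(estimator=estimator, n_perm=n_perm, seed=seed, scheme=scheme,
               truncate_h2=truncate_h2)
    res.settings = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    return res
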