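"""Twin-design estimators: ICC, Falconer h2, permutation null, confounders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adherit.exceptions import (DegenerateDataError, InsufficientDataError,
                                ValidationError)
from adherit.heritability import (PhenotypePair, TwinHeritabilityModel,
                                  confounder_screen, falconer_h2,
                                  intraclass_correlation,
                                  pearson_double_entry, permutation_pvalue,
                                  run_heritability_analysis,
                                  variance_equality)
from adherit.plate_io import PairRecord
from adherit.simulate import GenerativeConfig, simulate_pair_phenotypes


def _simulate_pairs(rng, n, r):
    """Bivariate normal pairs at intra-pair correlation r."""
    cov = [[1.0, r], [r, 1.0]]
    return rng.multivariate_normal([0, 0], cov, size=n)


class TestICC:
    def test_perfect_concordance(self):
        assert intraclass_correlation([(1, 1), (2, 2), (3, 3)]) \
            == pytest.approx(1.0)

    def test_member_order_exchangeability(self):
        rng = np.random.default_rng(0)
        pairs = _simulate_pairs(rng, 50, 0.5)
        swapped = pairs.copy()
        flip = rng.random(50) < 0.5
        swapped[flip] = swapped[flip, ::-1]
        assert intraclass_correlation(swapped) \
            == pytest.approx(intraclass_correlation(pairs))

    def test_recovers_generative_correlation(self):
        """10,000 pairs at true intra-pair correlation 0.60."""
        rng = np.random.default_rng(1)
        icc = intraclass_correlation(_simulate_pairs(rng, 10_000, 0.60))
        assert icc == pytest.approx(0.60, abs=0.02)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(DegenerateDataError):
            intraclass_correlation([(1, 1), (1, 1), (1, 1)])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            intraclass_correlation([(1, 2), (3, 4)])

    def test_matches_independent_oneway_icc(self):
        """Cross-check against pingouin's one-way random-effects ICC1."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        pairs = _simulate_pairs(rng, 40, 0.6)
        df = pd.DataFrame({
            "target": np.repeat(np.arange(40), 2),
            "rater": np.tile(["a", "b"], 40),
            "score": pairs.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="target", raters="rater",
                                       ratings="score")
        icc1 = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert intraclass_correlation(pairs) == pytest.approx(icc1, abs=1e-10)


class TestDoubleEntryPearson:
    def test_perfect_concordance(self):
        assert pearson_double_entry([(1, 1), (2, 2), (3, 3)]) \
            == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert pearson_double_entry([(-1, 1), (1, -1), (-2, 2)]) \
            == pytest.approx(-1.0)

    def test_matches_explicit_double_entry(self):
        """Equals np.corrcoef on the explicitly doubled list."""
        rng = np.random.default_rng(2)
        pairs = _simulate_pairs(rng, 30, 0.4)
        doubled = np.vstack([pairs, pairs[:, ::-1]])
        ref = np.corrcoef(doubled[:, 0], doubled[:, 1])[0, 1]
        assert pearson_double_entry(pairs) == pytest.approx(ref, abs=1e-12)

    def test_agrees_with_anova_icc_to_order_one_over_n(self):
        rng = np.random.default_rng(3)
        for n in (50, 500, 5000):
            pairs = _simulate_pairs(rng, n, 0.6)
            gap = abs(pearson_double_entry(pairs)
                      - intraclass_correlation(pairs))
            assert gap < 5.0 / n


class TestFalconer:
    def test_study_arithmetic(self):
        assert falconer_h2(0.60, 0.25) == pytest.approx(0.70)

    def test_no_excess_resemblance(self):
        assert falconer_h2(0.42, 0.42) == 0.0

    def test_hand_arithmetic(self):
        assert falconer_h2(0.5, 0.4) == pytest.approx(0.2)

    def test_raw_out_of_range_reported_and_truncation_optional(self):
        assert falconer_h2(0.9, 0.2) == pytest.approx(1.4)
        assert falconer_h2(0.9, 0.2, truncate=True) == 1.0
        assert falconer_h2(0.1, 0.4, truncate=True) == 0.0

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            falconer_h2(1.2, 0.0)


class TestPermutation:
    def _groups(self, rng, r_mz=0.8, r_sib=0.45, n=23):
        return (_simulate_pairs(rng, n, r_mz), _simulate_pairs(rng, n, r_sib))

    def test_same_seed_is_bit_identical(self):
        rng = np.random.default_rng(5)
        mz, sib = self._groups(rng)
        a = permutation_pvalue(mz, sib, n_perm=300, seed=9)
        b = permutation_pvalue(mz, sib, n_perm=300, seed=9)
        assert a == b

    def test_add_one_rule_bounds(self):
        rng = np.random.default_rng(6)
        mz, sib = self._groups(rng)
        res = permutation_pvalue(mz, sib, n_perm=200, seed=1)
        assert 1.0 / 201 <= res.p_value <= 1.0

    def test_extreme_statistic_attains_minimum_p(self):
        """Strong heritability at 200 pairs/group: no permuted h2 reaches
        the observed one, so p hits the add-one floor 1/(n_perm+1)."""
        rng = np.random.default_rng(7)
        mz = _simulate_pairs(rng, 200, 0.9)
        sib = _simulate_pairs(rng, 200, 0.45)
        res = permutation_pvalue(mz, sib, n_perm=10_000, seed=2)
        assert res.p_value == pytest.approx(1.0 / 10_001)

    def test_degenerate_values_propagate_error(self):
        flat = np.ones((5, 2))
        with pytest.raises(DegenerateDataError):
            permutation_pvalue(flat, flat, n_perm=10, seed=0)

    def test_null_calibration_type_I_error(self):
        """Null cohorts (h2=0, c2=0, 23+23 pairs): rejection rate at
        alpha=0.05 inside the binomial band, i.e. the permutation p is
        (super-)uniform."""
        rng = np.random.default_rng(8)
        alpha, n_rep = 0.05, 200
        rejections = 0
        for _ in range(n_rep):
            mz = rng.standard_normal((23, 2))
            sib = rng.standard_normal((23, 2))
            res = permutation_pvalue(mz, sib, n_perm=500,
                                     rng=np.random.default_rng(
                                         rng.integers(2**31)))
            rejections += res.p_value <= alpha
        band = 1.96 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rejections / n_rep - alpha) <= band

    def test_pair_label_scheme_available(self):
        rng = np.random.default_rng(9)
        mz, sib = self._groups(rng)
        res = permutation_pvalue(mz, sib, n_perm=100, seed=3,
                                 scheme="pair_labels")
        assert res.scheme == "pair_labels" and 0 < res.p_value <= 1


class TestModelFit:
    def _cohort_pairs(self, seed=0, **kw):
        cfg = GenerativeConfig(seed=seed, **kw)
        return simulate_pair_phenotypes(cfg).phenotype_pairs

    def test_results_carry_consistent_estimates(self):
        pairs = self._cohort_pairs(seed=21)
        res = TwinHeritabilityModel.from_pairs(pairs).fit(n_perm=500, seed=4)
        assert res.h2 == pytest.approx(2 * (res.r_mz - res.r_sib))
        assert -1 <= res.r_mz <= 1 and -1 <= res.r_sib <= 1
        assert res.n_mz == 23 and res.n_sib == 23
        assert "h2" in res.summary() or "h2" in res.summary().lower()

    def test_same_seed_bit_identical_results(self):
        pairs = self._cohort_pairs(seed=22)
        model = TwinHeritabilityModel.from_pairs(pairs)
        a = model.fit(n_perm=400, seed=5)
        b = model.fit(n_perm=400, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_group_swap_negates_h2(self):
        pairs = self._cohort_pairs(seed=23)
        flipped = [PhenotypePair(p.pair_id, "SIB" if p.zygosity == "MZ"
                                 else "MZ", p.y_a, p.y_b) for p in pairs]
        a = TwinHeritabilityModel.from_pairs(pairs).fit(n_perm=1, seed=0)
        b = TwinHeritabilityModel.from_pairs(flipped).fit(n_perm=1, seed=0)
        assert b.h2 == pytest.approx(-a.h2)

    def test_single_zygosity_group_rejected(self):
        pairs = [PhenotypePair(f"p{i}", "MZ", float(i), float(i) + 0.1)
                 for i in range(6)]
        with pytest.raises(InsufficientDataError):
            TwinHeritabilityModel.from_pairs(pairs)

    def test_member_permutation_leaves_fit_unchanged(self):
        pairs = self._cohort_pairs(seed=24)
        rng = np.random.default_rng(0)
        swapped = [PhenotypePair(p.pair_id, p.zygosity, p.y_b, p.y_a)
                   if rng.random() < 0.5 else p for p in pairs]
        a = TwinHeritabilityModel.from_pairs(pairs).fit(n_perm=1, seed=0)
        b = TwinHeritabilityModel.from_pairs(swapped).fit(n_perm=1, seed=0)
        assert b.r_mz == pytest.approx(a.r_mz)
        assert b.r_sib == pytest.approx(a.r_sib)
        assert b.h2 == pytest.approx(a.h2)

    @pytest.mark.parametrize("h2_true", [0.0, 0.3, 0.7])
    def test_parameter_recovery_is_unbiased(self, h2_true):
        """Mean estimate over 200 cohorts of 2,000 pairs/group within
        +/-0.02 of the generative h2."""
        ests = []
        for rep in range(200):
            cfg = GenerativeConfig(n_mz_pairs=2000, n_sib_pairs=2000,
                                   h2=h2_true, c2=0.1,
                                   seed=100_000 * (1 + int(h2_true * 10)) + rep)
            co = simulate_pair_phenotypes(cfg)
            ests.append(falconer_h2(
                intraclass_correlation(co.group_matrix("MZ")),
                intraclass_correlation(co.group_matrix("SIB"))))
        assert np.mean(ests) == pytest.approx(h2_true, abs=0.02)

    def test_unmatched_sample_ids_listed(self):
        recs = [PairRecord("p1", "MZ", "A", "B"),
                PairRecord("p2", "SIB", "C", "D")]
        with pytest.raises(ValidationError, match="D"):
            run_heritability_analysis({"A": 1.0, "B": 2.0, "C": 3.0}, recs,
                                      n_perm=1)

    def test_provenance_recorded(self):
        cfg = GenerativeConfig(seed=31)
        co = simulate_pair_phenotypes(cfg)
        res = run_heritability_analysis(co.phenotypes, co.pair_records,
                                        n_perm=50, seed=12)
        assert res.settings["config"]["seed"] == 12
        assert len(res.settings["config_hash"]) == 16


class TestConfounderScreen:
    def _table(self, rng, n=20, dependent=None):
        df = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "phenotype": rng.normal(40, 10, n),
            "age": rng.integers(12, 61, n),
            "sex": rng.choice(["F", "M"], n),
            "ethnicity": rng.choice(["White", "Black", "Asian"], n),
            "growth_class": rng.choice(["slow", "fast"], n),
            "transformation_time": rng.integers(20, 61, n),
        })
        if dependent:
            df["phenotype"] = df[dependent].astype(float)
        return df

    def test_null_covariates_yield_uniform_p(self):
        rng = np.random.default_rng(11)
        age_ps = [confounder_screen(self._table(rng))
                  .set_index("covariate").loc["age", "p_value"]
                  for _ in range(300)]
        assert stats.kstest(age_ps, "uniform").pvalue > 0.01

    def test_phenotype_equal_to_covariate_detected(self):
        rng = np.random.default_rng(12)
        screen = confounder_screen(self._table(rng, dependent="age"))
        row = screen.set_index("covariate").loc["age"]
        assert row["statistic"] == pytest.approx(1.0)
        assert row["p_value"] < 1e-10

    def test_constant_covariate_not_testable(self):
        rng = np.random.default_rng(13)
        df = self._table(rng)
        df["ethnicity"] = "White"
        row = confounder_screen(df).set_index("covariate").loc["ethnicity"]
        assert not row["testable"] and "constant" in row["note"]

    def test_all_five_covariates_screened_with_bonferroni(self):
        rng = np.random.default_rng(14)
        screen = confounder_screen(self._table(rng, n=40))
        assert set(screen["covariate"]) == {"age", "sex", "ethnicity",
                                            "growth_class",
                                            "transformation_time"}
        ok = screen[screen["testable"]]
        assert (ok["p_bonferroni"] >= ok["p_value"] - 1e-12).all()


class TestVarianceEquality:
    def test_null_calibration(self):
        rng = np.random.default_rng(15)
        ps = [variance_equality({"w": rng.normal(0, 1, 12),
                                 "b": rng.normal(0, 1, 12)}).p_value
              for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = variance_equality({"a": x, "b": list(x)})
        assert res.f_statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_variance_ratio_16_closed_form(self):
        """F=16 with n=20 per group: two-sided p = 2*sf(16, 19, 19)."""
        rng = np.random.default_rng(16)
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        a = (a - a.mean()) / a.std(ddof=1) * 4.0   # exact sd 4
        b = (b - b.mean()) / b.std(ddof=1)         # exact sd 1
        res = variance_equality({"a": a, "b": b})
        assert res.f_statistic == pytest.approx(16.0)
        assert res.p_value == pytest.approx(2 * stats.f.sf(16, 19, 19))
        assert res.p_value < 1e-3

    def test_more_than_two_groups_flagged_pairwise(self):
        rng = np.random.default_rng(17)
        res = variance_equality({k: rng.standard_normal(10)
                                 for k in "abc"})
        assert res.pairwise is not None and len(res.pairwise) == 3
        assert "Bonferroni" in res.note

    def test_zero_variance_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            variance_equality({"a": [1.0, 1.0], "b": [1.0, 2.0]})


@given(r_mz=st.floats(-1, 1), r_sib=st.floats(-1, 1))
@settings(max_examples=100, deadline=None)
def test_falconer_antisymmetry_property(r_mz, r_sib):
    assert falconer_h2(r_mz, r_sib) == pytest.approx(-falconer_h2(r_sib, r_mz))
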