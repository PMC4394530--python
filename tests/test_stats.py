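"""Cohort statistics: classification boundaries, median split, and every
statistic checked against an independent textbook/scipy oracle, including
on batches of random inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from ldaep.simulate import CohortSpec, generate_cohort
from ldaep.stats import (
    chi_square_2x2,
    classify_response,
    cohens_d,
    glm_group_sex,
    ks_normality,
    median_split,
    paired_t,
    pearson_r,
    relative_odds,
    stratify_cohort,
    build_summary_tables,
    two_sample_t,
)


class TestClassification:
    def test_response_above_half_reduction(self):
        s = classify_response(30, 14)
        assert s.responder and s.bdi_change_pct == pytest.approx(53.333, abs=1e-3)

    def test_exactly_fifty_percent_is_not_response(self):
        assert not classify_response(30, 15).responder

    def test_remitter_boundary_strict(self):
        assert not classify_response(30, 10).remitter
        assert classify_response(30, 9).remitter

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            classify_response(0, 5)


class TestMedianSplit:
    def test_odd_n_distinct_values_split_20_21(self, rng):
        v = rng.permutation(np.linspace(0.1, 2.5, 41))
        labels = median_split(v)
        assert (labels == "low").sum() == 20
        assert (labels == "high").sum() == 21

    def test_even_case_interpolated_median(self):
        labels = median_split([1.0, 2.0, 3.0, 4.0])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_order_invariance(self, rng):
        v = rng.normal(size=31)
        perm = rng.permutation(31)
        assert np.array_equal(median_split(v)[perm], median_split(v[perm]))

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            median_split([1.0, 1.0, 1.0])


class TestTwoSampleT:
    def test_matches_scipy_from_stats_on_random_inputs(self, rng):
        for _ in range(1000):
            na, nb = rng.integers(2, 40, size=2)
            ma, mb = rng.normal(0, 5, size=2)
            sa, sb = rng.uniform(0.2, 5, size=2)
            for mode, equal_var in (("pooled", True), ("welch", False)):
                r = two_sample_t((na, ma, sa), (nb, mb, sb), mode=mode)
                t_ref, p_ref = sstats.ttest_ind_from_stats(
                    ma, sa, na, mb, sb, nb, equal_var=equal_var)
                assert r.value == pytest.approx(t_ref, rel=1e-9, abs=1e-12)
                assert r.p == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_welch_df_never_exceeds_pooled_df(self, rng):
        for _ in range(200):
            na, nb = rng.integers(2, 30, size=2)
            sa, sb = rng.uniform(0.2, 5, size=2)
            r = two_sample_t((na, 0.0, sa), (nb, 1.0, sb), mode="welch")
            assert r.df <= na + nb - 2 + 1e-9

    def test_welch_equals_pooled_for_equal_sizes_and_variances(self):
        a, b = (12, 1.0, 2.0), (12, 3.0, 2.0)
        rw = two_sample_t(a, b, mode="welch")
        rp = two_sample_t(a, b, mode="pooled")
        assert rw.value == pytest.approx(rp.value, abs=1e-12)
        assert rw.df == pytest.approx(rp.df, abs=1e-9)

    def test_identical_groups_null(self):
        r = two_sample_t((10, 2.0, 1.0), (10, 2.0, 1.0), mode="pooled")
        assert r.value == 0.0 and r.p == pytest.approx(1.0)

    def test_raw_value_input(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 20)
        r = two_sample_t(a, b, mode="welch")
        t_ref, p_ref = sstats.ttest_ind(a, b, equal_var=False)
        assert r.value == pytest.approx(t_ref)
        assert r.p == pytest.approx(p_ref)

    def test_zero_variance_equal_means_undefined(self):
        with pytest.raises(ValueError):
            two_sample_t((5, 1.0, 0.0), (5, 1.0, 0.0), mode="pooled")


class TestPairedT:
    def test_identity_gives_zero(self):
        r = paired_t([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert r.value == 0.0 and r.p == pytest.approx(1.0)

    def test_constant_shift_undefined(self):
        with pytest.raises(ValueError):
            paired_t([3.0, 4.0, 5.0], [4.0, 5.0, 6.0])

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(500):
            n = rng.integers(3, 30)
            pre = rng.normal(10, 3, n)
            post = pre + rng.normal(-1, 2, n)
            r = paired_t(pre, post)
            t_ref, p_ref = sstats.ttest_rel(pre, post)
            assert r.value == pytest.approx(t_ref, rel=1e-9, abs=1e-12)
            assert r.p == pytest.approx(p_ref, rel=1e-9, abs=1e-12)
            assert r.df == n - 1


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        assert chi_square_2x2([[10, 10], [20, 20]]).value == pytest.approx(0.0)

    def test_matches_brute_force_and_scipy_on_random_tables(self, rng):
        for _ in range(1000):
            tbl = rng.integers(1, 60, size=(2, 2)).astype(float)
            r = chi_square_2x2(tbl)
            # brute force sum (O - E)^2 / E
            row, col, n = tbl.sum(1), tbl.sum(0), tbl.sum()
            exp = np.outer(row, col) / n
            assert r.value == pytest.approx((((tbl - exp) ** 2) / exp).sum(), rel=1e-9)
            ref = sstats.chi2_contingency(tbl, correction=False)
            assert r.value == pytest.approx(ref.statistic, rel=1e-9)
            assert r.p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.integers(1, 80), b=st.integers(1, 80),
        c=st.integers(1, 80), d=st.integers(1, 80),
    )
    def test_invariant_to_transpose_and_row_swap(self, a, b, c, d):
        tbl = np.array([[a, b], [c, d]], dtype=float)
        v = chi_square_2x2(tbl).value
        assert chi_square_2x2(tbl.T).value == pytest.approx(v)
        assert chi_square_2x2(tbl[::-1]).value == pytest.approx(v)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 10]])


class TestRelativeOdds:
    def test_no_association_gives_unity(self):
        r = relative_odds((4, 8), (10, 20))
        assert r.value == pytest.approx(1.0)

    def test_zero_cell_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="continuity"):
            relative_odds((0, 5), (10, 20))

    def test_conventional_or_also_reported(self):
        r = relative_odds((11, 9), (16, 25))
        assert r.extra["conventional_or"] == pytest.approx(
            (11 / 9) / (5 / 16), rel=1e-9)


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d((10, 5.0, 2.0), (12, 5.0, 3.0)).value == 0.0

    def test_doubling_sds_halves_d(self):
        d1 = cohens_d((10, 0.0, 2.0), (10, 3.0, 2.0)).value
        d2 = cohens_d((10, 0.0, 4.0), (10, 3.0, 4.0)).value
        assert d2 == pytest.approx(d1 / 2)

    def test_matches_pooled_formula_on_random_inputs(self, rng):
        for _ in range(500):
            na, nb = rng.integers(2, 40, size=2)
            ma, mb = rng.normal(0, 5, size=2)
            sa, sb = rng.uniform(0.2, 5, size=2)
            d = cohens_d((na, ma, sa), (nb, mb, sb)).value
            sp = np.sqrt(((na - 1) * sa**2 + (nb - 1) * sb**2) / (na + nb - 2))
            assert d == pytest.approx(abs(ma - mb) / sp, rel=1e-12)


class TestGlm:
    def test_group_f_matches_pooled_t_squared_without_sex_effect(self, rng):
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        g = np.repeat(["a", "b"], 30)
        sex = np.tile(["M", "F"], 30)  # balanced, orthogonal to group
        f = glm_group_sex(y, g, sex)
        t = two_sample_t(y[:30], y[30:], mode="pooled")
        # the sex term absorbs O(1/df) chance variance, shifting F slightly
        assert f.value == pytest.approx(t.value**2, rel=0.1)

    def test_perfect_separation_is_significant(self, rng):
        y = np.concatenate([np.zeros(15), np.ones(15)]) + rng.normal(0, 1e-4, 30)
        g = np.repeat(["a", "b"], 15)
        sex = np.tile(["M", "F"], 15)
        assert glm_group_sex(y, g, sex).p < 1e-6

    def test_type_i_error_under_null(self):
        """Outcome independent of group: rejection rate at alpha = 0.05
        stays near 5% over 1000 seeded replicates."""
        rng = np.random.default_rng(42)
        rejections = 0
        n = 40
        g = np.repeat(["a", "b"], n // 2)
        sex = np.tile(["M", "F"], n // 2)
        for _ in range(1000):
            y = rng.normal(size=n)
            if glm_group_sex(y, g, sex).p < 0.05:
                rejections += 1
        assert 30 <= rejections <= 70  # 5% +- ~3 binomial SD

    def test_single_sex_rejected(self):
        with pytest.raises(ValueError):
            glm_group_sex([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"],
                          ["M", "M", "M", "M"])


class TestKs:
    def test_large_normal_sample_passes(self):
        rng = np.random.default_rng(8)
        assert ks_normality(rng.normal(3, 2, 1000)).p > 0.05

    def test_uniform_sample_fails(self):
        rng = np.random.default_rng(8)
        assert ks_normality(rng.uniform(0, 1, 1000)).p < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([2.0] * 10)


class TestPearson:
    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = pearson_r(x, y)
        ref_r, ref_p = sstats.pearsonr(x, y)
        assert r.value == pytest.approx(ref_r)
        assert r.p == pytest.approx(ref_p)


@pytest.fixture(scope="module")
def strat():
    cohort = generate_cohort(CohortSpec(n_subjects=400, seed=17))
    return stratify_cohort(cohort, slope_column="true_slope_n1p2")


class TestSummaryTables:
    def test_tables_render_and_reproduce_configured_coupling(self, strat):
        tables = build_summary_tables(
            strat, slope_columns={"N1/P2": "true_slope_n1p2"})
        t3 = tables["ldaep_group"]
        row = t3[t3.variable == "BDI change (%)"].iloc[0]
        low_mean = float(row["low"].split(" ±")[0])
        high_mean = float(row["high"].split(" ±")[0])
        # 3 SE Monte-Carlo tolerance at n = 200 per group (+ BDI rounding)
        assert abs(low_mean - 37.2) < 3 * 40.9 / np.sqrt(200) + 0.5
        assert abs(high_mean - 70.2) < 3 * 36.2 / np.sqrt(200) + 0.5

    def test_responder_rate_is_group_fraction(self, strat):
        tables = build_summary_tables(
            strat, slope_columns={"N1/P2": "true_slope_n1p2"})
        t3 = tables["ldaep_group"]
        rate_row = t3[t3.variable == "Responder rate (%)"].iloc[0]
        m = strat["ldaep_group"] == "high"
        assert float(rate_row["high"]) == pytest.approx(
            100.0 * strat.loc[m, "responder"].mean(), abs=0.05)

    def test_single_sex_stratum_marked_not_computable(self):
        cohort = generate_cohort(CohortSpec(n_subjects=40, male_fraction=0.0, seed=2))
        strat = stratify_cohort(cohort, slope_column="true_slope_n1p2")
        tables = build_summary_tables(
            strat, slope_columns={"N1/P2": "true_slope_n1p2"})
        sex_row = tables["response"][
            tables["response"].variable == "Sex (male/female)"].iloc[0]
        assert sex_row["p"] == "n/a"
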