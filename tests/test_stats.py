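"""ANCOVA, effect sizes, post hoc patterns, demographics tests and ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import roitex as rt
from roitex.stats import assemble_pattern, bonferroni_adjust, fit_ancova


class TestOneWayAnova:
    def test_hand_computed_f(self):
        """Groups {1,2,3} and {2,3,4}: SSB=1.5, SSW=4, F=(1.5/1)/(4/4)=1.5."""
        y = np.array([1, 2, 3, 2, 3, 4], dtype=float)
        g = np.array(["a"] * 3 + ["b"] * 3)
        F, p = rt.one_way_anova(y, g)
        assert F == pytest.approx(1.5)
        assert p == pytest.approx(sps.f.sf(1.5, 1, 4))

    def test_identical_means_f_zero(self):
        y = np.array([1, 2, 3, 3, 2, 1], dtype=float)
        g = np.array(["a"] * 3 + ["b"] * 3)
        F, _ = rt.one_way_anova(y, g)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rt.one_way_anova(np.array([1.0, 1.0, 2.0, 2.0]),
                             np.array(["a", "a", "b", "b"]))


class TestAncova:
    def test_no_covariates_reduces_to_anova(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        res = rt.ancova_group_test(y, g)
        F, p = rt.one_way_anova(y, g)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert (res.df1, res.df2) == (2, 27)

    def test_two_group_hand_example(self):
        y = np.array([1, 2, 3, 2, 3, 4], dtype=float)
        g = np.array(["a"] * 3 + ["b"] * 3)
        res = rt.ancova_group_test(y, g)
        assert res.F == pytest.approx(1.5)
        assert (res.df1, res.df2) == (1, 4)

    def test_orthogonal_null_covariate(self):
        """A covariate orthogonal to the dummies and to y leaves both sums of
        squares unchanged; only df2 drops by one."""
        rng = np.random.default_rng(2)
        y = rng.normal(size=24)
        g = np.repeat(["a", "b", "c"], 8)
        # Gram-Schmidt a covariate against [1, dummies, y]
        d_b = (g == "b").astype(float)
        d_c = (g == "c").astype(float)
        basis = np.column_stack([np.ones(24), d_b, d_c, y])
        cov = rng.normal(size=24)
        cov -= basis @ np.linalg.lstsq(basis, cov, rcond=None)[0]
        plain = rt.ancova_group_test(y, g)
        adjusted = rt.ancova_group_test(y, g, covariates=cov)
        assert adjusted.df2 == plain.df2 - 1
        # same SS ratio, F rescaled only by the df2 change
        assert adjusted.F == pytest.approx(plain.F * (plain.df2 - 1) / plain.df2,
                                           rel=1e-9)

    def test_adjusted_means_at_covariate_means(self):
        rng = np.random.default_rng(3)
        n = 60
        g = np.repeat(["a", "b", "c"], n // 3)
        cov = rng.normal(10, 2, size=n)
        y = 5.0 + 2.0 * (g == "b") + 3.0 * (g == "c") + 0.5 * cov
        res = rt.ancova_group_test(y, g, covariates=cov)
        base = 5.0 + 0.5 * cov.mean()
        assert res.adjusted_means["a"] == pytest.approx(base)
        assert res.adjusted_means["b"] == pytest.approx(base + 2.0)
        assert res.adjusted_means["c"] == pytest.approx(base + 3.0)

    def test_rank_deficient_design_names_columns(self):
        y = np.arange(12, dtype=float)
        g = np.repeat(["a", "b", "c"], 4)
        cov = pd.DataFrame({"x1": np.ones(12), "x2": np.arange(12, dtype=float)})
        with pytest.raises(ValueError, match="x1"):
            rt.ancova_group_test(y, g, covariates=cov)

    def test_eta_identity_on_results(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=36)
        g = np.repeat(["a", "b", "c"], 12)
        res = rt.ancova_group_test(y, g, covariates=rng.normal(size=36))
        assert res.partial_eta_sq == pytest.approx(
            res.F * res.df1 / (res.F * res.df1 + res.df2), abs=1e-12
        )

    def test_posthoc_invariant_to_label_permutation(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30) + np.repeat([0.0, 1.0, 2.0], 10)
        g = np.repeat(["a", "b", "c"], 10)
        res1 = rt.ancova_group_test(y, g)
        swap = {"a": "c", "b": "b", "c": "a"}
        res2 = rt.ancova_group_test(y, np.vectorize(swap.get)(g))
        p1 = res1.posthoc.pairwise_p_adj
        p2 = res2.posthoc.pairwise_p_adj
        # the a-b contrast becomes the b-c contrast under the swap, etc.
        assert p1[("a", "b")] == pytest.approx(p2[("b", "c")], rel=1e-9)
        assert p1[("a", "c")] == pytest.approx(p2[("a", "c")], rel=1e-9)
        assert p1[("b", "c")] == pytest.approx(p2[("a", "b")], rel=1e-9)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rt.ancova_group_test(np.ones(4), np.array(["a", "a", "b", "b"]),
                                 covariates=np.arange(4.0))


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [
            (50.755, 2, 442, 0.187),  # strongest medial-temporal volume row
            (19.839, 2, 442, 0.082),  # strongest texture row
            (0.0, 2, 442, 0.0),
        ],
    )
    def test_published_scale_values(self, F, df1, df2, expected):
        assert round(rt.partial_eta_squared(F, df1, df2), 3) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rt.partial_eta_squared(-1.0, 2, 442)
        with pytest.raises(ValueError):
            rt.partial_eta_squared(1.0, 0, 442)


class TestBonferroni:
    def test_adjustment_and_cap(self):
        assert bonferroni_adjust(0.02, 3) == pytest.approx(0.06)
        assert bonferroni_adjust(0.5, 3) == 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5)

    def test_posthoc_uses_model_error_variance(self):
        """With equal group means the adjusted pairwise p-values are large;
        with a huge separation they are near zero."""
        rng = np.random.default_rng(6)
        g = np.repeat(["a", "b", "c"], 15)
        flat = rng.normal(size=45)
        res = rt.ancova_group_test(flat, g)
        assert all(p > 0.05 for p in res.posthoc.pairwise_p_adj.values()) or res.p > 0.05
        sep = flat + np.repeat([0.0, 50.0, 100.0], 15)
        res2 = rt.ancova_group_test(sep, g)
        assert all(p < 1e-6 for p in res2.posthoc.pairwise_p_adj.values())
        assert res2.posthoc.pattern == "a < b < c"


class TestPatternAssembly:
    LABELS = ["a", "b", "c"]

    def _pat(self, means, sig, omnibus=True):
        sig_pairs = {frozenset(p) for p in sig}
        return assemble_pattern(self.LABELS, means, sig_pairs, omnibus)

    def test_full_ordering_descending(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert self._pat(means, [("a", "b"), ("a", "c"), ("b", "c")]) == "a > b > c"

    def test_full_ordering_ascending(self):
        means = {"a": 1.0, "b": 2.0, "c": 3.0}
        assert self._pat(means, [("a", "b"), ("a", "c"), ("b", "c")]) == "a < b < c"

    def test_two_above_one(self):
        means = {"a": 3.0, "b": 2.9, "c": 1.0}
        assert self._pat(means, [("a", "c"), ("b", "c")]) == "a, b > c"

    def test_one_below_two(self):
        means = {"a": 1.0, "b": 2.0, "c": 2.1}
        assert self._pat(means, [("a", "b"), ("a", "c")]) == "a < b, c"

    def test_single_significant_pair(self):
        means = {"a": 1.0, "b": 1.5, "c": 2.0}
        assert self._pat(means, [("a", "c")]) == "a < c"
        means2 = {"a": 2.0, "b": 1.5, "c": 1.0}
        assert self._pat(means2, [("a", "c")]) == "a > c"

    def test_middle_reference(self):
        means = {"a": 2.0, "b": 3.0, "c": 1.0}
        assert self._pat(means, [("a", "b"), ("a", "c"), ("b", "c")]) == "b > a > c"

    def test_empty_when_omnibus_not_significant(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert self._pat(means, [("a", "c")], omnibus=False) == ""

    def test_empty_when_no_pair_significant(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert self._pat(means, []) == ""


class TestChiSquare:
    def test_homogeneous_table(self):
        chi2, p = rt.chi_square_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed(self):
        """Expected counts all 15: chi2 = 4 * 25/15 = 20/3."""
        chi2, p = rt.chi_square_test([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(20.0 / 3.0)
        assert p == pytest.approx(sps.chi2.sf(20.0 / 3.0, 1))

    def test_reconstructed_sex_distribution(self):
        """Female counts 116/183, 57/111, 96/155 reproduce the reported
        non-significant sex difference (p ~ 0.102)."""
        table = [[116, 57, 96], [183 - 116, 111 - 57, 155 - 96]]
        _, p = rt.chi_square_test(table)
        assert round(p, 3) == 0.102

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            rt.chi_square_test([[0, 0], [5, 5]])


def icc21_oracle(a, b):
    """Hand mean-squares ICC(2,1) for two raters."""
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((data - data.mean(axis=1, keepdims=True)
          - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        / ((n - 1) * (k - 1))
    )
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = rt.icc_two_rater(a, a)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_mean_squares_oracle(self):
        a = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        b = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        res = rt.icc_two_rater(a, b)
        assert res.icc == pytest.approx(icc21_oracle(a, b), abs=1e-9)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(10):
            a, b = rng.normal(size=200), rng.normal(size=200)
            if abs(rt.icc_two_rater(a, b).icc) < 0.15:
                hits += 1
        assert hits >= 9

    def test_zero_between_subject_variance_flagged(self):
        res = rt.icc_two_rater(np.full(6, 2.0), np.full(6, 2.0))
        assert res.flagged

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            rt.icc_two_rater(np.ones(3), np.ones(3))


class TestResultsTables:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort_tables():
        from roitex.pipeline import RunConfig, extract_cohort_features
        from roitex.studies import null_cohort_spec

        cohort = rt.generate_cohort(null_cohort_spec(n_per_group=(10, 10, 10), seed=21))
        features = extract_cohort_features(cohort, RunConfig(include_lobe_rows=False))
        return features, cohort.subjects

    def test_texture_covariate_is_regional_volume_not_tbv(self, cohort_tables):
        """Scrambling tbv_cc changes volume rows but leaves texture rows alone;
        scrambling only the regional volumes does the opposite."""
        features, subjects = cohort_tables
        tex0, _ = rt.build_results_table(features, subjects, "texture")
        vol0, _ = rt.build_results_table(features, subjects, "volume")
        rng = np.random.default_rng(0)
        f2 = features.copy()
        f2["tbv_cc"] = f2["tbv_cc"] * rng.uniform(0.5, 1.5, size=len(f2))
        tex2, _ = rt.build_results_table(f2, subjects, "texture")
        vol2, _ = rt.build_results_table(f2, subjects, "volume")
        np.testing.assert_allclose(tex2["F"], tex0["F"])
        assert not np.allclose(vol2["F"], vol0["F"])

    def test_eta_identity_for_every_row(self, cohort_tables):
        features, subjects = cohort_tables
        for kind in ("volume", "texture"):
            tab, _ = rt.build_results_table(features, subjects, kind)
            np.testing.assert_allclose(
                tab["partial_eta_sq"],
                tab["F"] * tab["df1"] / (tab["F"] * tab["df1"] + tab["df2"]),
                atol=1e-12,
            )

    def test_volume_df2_matches_design(self, cohort_tables):
        """n=30, 3 groups, 4 covariates -> df2 = 30 - 3 - 4 = 23."""
        features, subjects = cohort_tables
        tab, _ = rt.build_results_table(features, subjects, "volume")
        assert (tab["df1"] == 2).all()
        assert (tab["df2"] == 23).all()

    def test_long_table_has_three_pairs_per_roi(self, cohort_tables):
        features, subjects = cohort_tables
        _, long = rt.build_results_table(features, subjects, "texture")
        assert long.groupby("roi")["pair"].count().eq(3).all()
        assert set(long["pair"]) == {"a-b", "a-c", "b-c"}

    def test_missing_covariate_column_rejected(self, cohort_tables):
        features, subjects = cohort_tables
        with pytest.raises(ValueError, match="lacks"):
            rt.build_results_table(features, subjects.drop(columns=["education"]),
                                   "volume")

    def test_demographics_table(self, cohort_tables):
        features, subjects = cohort_tables
        subj = subjects.merge(
            features.groupby("subject_id")["tbv_cc"].first(), on="subject_id"
        )
        tab = rt.demographics_table(subj)
        assert {"Age, years", "Education, years", "MMSE, points",
                "Total brain volume, cc", "Sex, female, %"} <= set(tab["variable"])
        assert tab["p"].between(0, 1).all()
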