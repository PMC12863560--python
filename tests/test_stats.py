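"""Outlier screening, Welch tests, correlations, curve-comparison F tests,
mixed ANOVA."""

import numpy as np
import pytest
from scipy import stats as sps

import qscan


class TestGrubbs:
    def test_hand_computed_statistic(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0])
        res = qscan.grubbs_test(vals, list("abcd"))
        expected = np.max(np.abs(vals - vals.mean())) / vals.std(ddof=1)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_critical_value_closed_form(self):
        for n in range(3, 31):
            t = sps.t.ppf(1 - 0.05 / (2 * n), n - 2)
            expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
            assert qscan.stats.grubbs_critical_value(n) == pytest.approx(
                expected, rel=1e-12)

    def test_reference_q0_outlier(self, fitted_variables):
        """On the 12-subject fitted Q0 values the screen flags subject K;
        mean and SEM match the published pre-exclusion values exactly as
        arithmetic on the (1-decimal) published Q0 values."""
        variables, _ = fitted_variables
        res = qscan.grubbs_test(variables.column("q0"), variables.subjects)
        assert res.outlier_id == "K"
        # published arithmetic on the printed Q0 column
        printed = [2.7, 3.5, 4.0, 2.0, 4.3, 3.1, 2.2, 2.2, 2.1, 3.1, 8.5, 3.9]
        pub = qscan.grubbs_test(printed, ids=list("ABCDEFGHIJKL"))
        assert pub.outlier_id == "K"
        assert pub.sample_mean == pytest.approx(3.46667, abs=5e-6)
        assert pub.sample_sem == pytest.approx(0.51188, abs=5e-6)

    def test_zero_variance_no_outlier(self):
        res = qscan.grubbs_test([2.0, 2.0, 2.0, 2.0])
        assert res.outlier_id is None
        assert np.isnan(res.statistic)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            qscan.grubbs_test([1.0, 2.0])


class TestWelch:
    def test_closed_form_small_sample(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = qscan.welch_t(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t_hand = (a.mean() - b.mean()) / se
        df_hand = (a.var(ddof=1) / 3 + b.var(ddof=1) / 3) ** 2 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)

    def test_identical_groups(self):
        res = qscan.welch_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_reduces_to_student_when_balanced(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        # force equal sample variances by standardizing
        a = (a - a.mean()) / a.std(ddof=1)
        b = (b - b.mean()) / b.std(ddof=1) + 1.0
        welch = qscan.welch_t(a, b)
        student = sps.ttest_ind(a, b, equal_var=True)
        assert welch.t == pytest.approx(float(student.statistic), rel=1e-10)
        assert welch.df == pytest.approx(14.0, rel=1e-10)

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            qscan.welch_t([1.0], [2.0, 3.0])


class TestPearsonMatrix:
    def test_toy_columns_match_hand_formula(self):
        t = qscan.VariableTable(["a", "b", "c"], ["x", "y"],
                                [[1.0, 2.0], [2.0, 1.0], [4.0, 6.0]])
        pm = qscan.pearson_matrix(t)
        x, y = t.column("x"), t.column("y")
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / ((len(x) - 1) * x.std(ddof=1) * y.std(ddof=1)))
        assert pm.r.loc["x", "y"] == pytest.approx(r_hand, rel=1e-12)
        assert pm.r.loc["x", "x"] == 1.0

    def test_zero_variance_column_flagged(self):
        t = qscan.VariableTable(["a", "b", "c"], ["x", "y"],
                                [[1.0, 2.0], [1.0, 1.0], [1.0, 6.0]])
        pm = qscan.pearson_matrix(t)
        assert ("x", "y") in pm.undefined
        assert np.isfinite(pm.r.values).all()

    def test_reference_q0_dose_correlations(self, table1, table2):
        """Demand intensity correlates with intake at the four highest doses
        and with none of the three lowest."""
        keep = table2.subjects
        idx = [table1.subjects.index(s) for s in keep]
        cols = [f"d{d:g}" for d in table1.doses]
        values = np.column_stack([table1.responses[idx], table2.values])
        t13 = qscan.VariableTable(keep, cols + table2.variables, values)
        pm = qscan.pearson_matrix(t13)
        high = ["d0.1", "d0.32", "d0.56", "d1"]
        low = ["d0", "d0.01", "d0.032"]
        for d in high:
            assert pm.p.loc["q0", d] < 0.05, d
        for d in low:
            assert pm.p.loc["q0", d] >= 0.05, d


class TestCompareGaussianCurves:
    def test_reference_amplitude_split(self, table1, table2):
        cohort = table1.subset(table2.subjects)
        split = qscan.median_split(table2.as_mapping("amplitude"), "amplitude")
        res = qscan.compare_gaussian_curves(cohort, split)
        assert (res.df_num, res.df_den) == (3, 60)
        assert res.f_statistic == pytest.approx(4.923, abs=0.02)
        assert res.p_value == pytest.approx(0.0040, abs=0.0005)

    def test_identical_groups_give_f_near_zero(self, table1):
        # two copies of the same subjects: separate fits gain nothing
        doses = table1.doses
        rows = np.vstack([table1.responses[:2]] * 2)
        cohort = qscan.CohortTable(["a1", "a2", "b1", "b2"], doses, rows)
        res = qscan.compare_gaussian_curves(cohort, (["a1", "a2"], ["b1", "b2"]))
        assert res.f_statistic == pytest.approx(0.0, abs=1e-6)

    def test_f_identity_and_nesting(self, table1, table2):
        cohort = table1.subset(table2.subjects)
        split = qscan.median_split(table2.as_mapping("mean"), "mean")
        res = qscan.compare_gaussian_curves(cohort, split)
        assert res.separate_sse <= res.shared_sse
        f_hand = ((res.shared_sse - res.separate_sse) / res.df_num) / (
            res.separate_sse / res.df_den)
        assert res.f_statistic == pytest.approx(f_hand, rel=1e-12)
        assert res.f_statistic >= 0

    def test_small_group_rejected(self, table1):
        with pytest.raises(ValueError):
            qscan.compare_gaussian_curves(table1, ([], table1.subjects))


class TestCompareDemandCurves:
    def test_design_degrees_of_freedom(self, table1, table2):
        cohort = table1.subset(table2.subjects)
        split = qscan.median_split(table2.as_mapping("amplitude"), "amplitude")
        res = qscan.compare_demand_curves(cohort, split, k=2.4)
        # 2 groups x 6 prices, 4 separate parameters
        assert (res.df_num, res.df_den) == (2, 8)
        for scope in ("alpha", "q0"):
            r1 = qscan.compare_demand_curves(cohort, split, k=2.4, scope=scope)
            assert (r1.df_num, r1.df_den) == (1, 8)

    def test_published_values_at_template_k(self, table1, table2,
                                            reference_clusters):
        """The published F(2,8) statistics correspond to the demand template
        constant k = 4; all three partitions reproduce at that k."""
        cohort = table1.subset(table2.subjects)
        amp = qscan.median_split(table2.as_mapping("amplitude"), "amplitude")
        mean = qscan.median_split(table2.as_mapping("mean"), "mean")
        for part, expect in [(amp, 2.9), (mean, 3.9), (reference_clusters, 4.8)]:
            res = qscan.compare_demand_curves(cohort, part, k=4.0)
            assert res.f_statistic == pytest.approx(expect, abs=0.06)

    def test_ordering_preserved_at_calibrated_k(self, table1, table2,
                                                fitted_variables,
                                                reference_clusters):
        """Whatever the k convention, clusters separate demand curves more
        than the mean split, which separates more than the amplitude split."""
        _, k = fitted_variables
        cohort = table1.subset(table2.subjects)
        amp = qscan.median_split(table2.as_mapping("amplitude"), "amplitude")
        mean = qscan.median_split(table2.as_mapping("mean"), "mean")
        f = {name: qscan.compare_demand_curves(cohort, part, k=k).f_statistic
             for name, part in [("amp", amp), ("mean", mean),
                                ("clusters", reference_clusters)]}
        assert f["clusters"] > f["mean"] > f["amp"]

    def test_identical_groups_f_near_zero(self, table1):
        rows = np.vstack([table1.responses[:2]] * 2)
        cohort = qscan.CohortTable(["a1", "a2", "b1", "b2"], table1.doses, rows)
        res = qscan.compare_demand_curves(cohort, (["a1", "a2"], ["b1", "b2"]),
                                          k=2.0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-6)


class TestRmAnova:
    def test_hand_computed_sums_of_squares(self):
        """Balanced 2 groups x 2 subjects x 3 doses; compare against a
        manual mixed-model SS partition."""
        doses = np.array([0.1, 0.32, 1.0])
        resp = np.array([
            [10.0, 20.0, 8.0],
            [12.0, 24.0, 9.0],
            [20.0, 40.0, 15.0],
            [22.0, 44.0, 18.0],
        ])
        cohort = qscan.CohortTable(list("wxyz"), doses, resp)
        res = qscan.rm_anova(cohort, (["w", "x"], ["y", "z"]), scale="raw")
        y = resp
        grand = y.mean()
        groups = [y[:2], y[2:]]
        n_per, n_dose = 2, 3
        ss_group = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        subj_means = y.mean(axis=1)
        ss_subj = n_dose * np.sum((subj_means - grand) ** 2)
        ss_subj_within = ss_subj - ss_group
        dose_means = y.mean(axis=0)
        ss_dose = 2 * n_per * np.sum((dose_means - grand) ** 2)
        cell = np.array([g.mean(axis=0) for g in groups])
        ss_cells = n_per * np.sum((cell - grand) ** 2)
        ss_inter = ss_cells - ss_group - ss_dose
        f_group = (ss_group / 1) / (ss_subj_within / 2)
        assert res.effect("group")["F"] == pytest.approx(f_group, rel=1e-9)
        assert res.effect("dose")["df1"] == 2
        assert res.effect("interaction")["df1"] == 2

    def test_group_effect_vanishes_for_duplicated_profiles(self, table1):
        rows = np.vstack([table1.responses[:3]] * 2)
        cohort = qscan.CohortTable(list("abcdef"), table1.doses, rows)
        res = qscan.rm_anova(cohort, (list("abc"), list("def")))
        assert res.effect("group")["F"] == pytest.approx(0.0, abs=1e-9)

    def test_epsilon_within_bounds_and_corrected_df(self, table1, table2):
        cohort = table1.subset(table2.subjects)
        split = qscan.median_split(table2.as_mapping("amplitude"), "amplitude")
        res = qscan.rm_anova(cohort, split)
        n_levels = int(np.sum(cohort.doses > 0))
        assert 1.0 / (n_levels - 1) < res.epsilon <= 1.0
        dose = res.effect("dose")
        assert dose["df1_gg"] == pytest.approx(res.epsilon * dose["df1"])
        # group main effect in the published ballpark on the log scale
        assert res.effect("group")["F"] == pytest.approx(5.638, rel=0.10)
        assert res.effect("group")["df2"] == 9
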