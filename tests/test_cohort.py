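"""Cohort statistics: chi-square, t-tests, ANOVA/Tukey, inter-observer."""

import numpy as np
import pytest
from scipy import stats

from sevkit import (
    ColorSummary,
    ContingencyTable,
    PatientRecord,
    anova_posthoc,
    chi_square_test,
    cohort_to_frame,
    interobserver_comparison,
    two_sample_t,
    two_sample_t_from_samples,
)

from _oracles import chi_square_loop, pooled_t_ci


def _summary(L=66.0, a=7.0, b=16.0):
    return ColorSummary(L, a, b, 1.0, 1.0, 1.0, 100)


def _record(i, arm="Bepanthen", dsev=300.0, g1=1, g2=1):
    return PatientRecord(
        patient_id=f"P{i}",
        arm=arm,
        control_summary=_summary(),
        delta_sev=dsev,
        grades={"obs1": g1, "obs2": g2},
    )


class TestChiSquare:
    def test_identical_row_proportions_give_unit_p(self):
        t = ContingencyTable(np.array([[10, 20, 30], [20, 40, 60]]))
        r = chi_square_test(t)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 40, size=(2, 2))
            r = chi_square_test(ContingencyTable(counts))
            stat, df = chi_square_loop(counts.tolist())
            assert r.statistic == pytest.approx(stat, abs=1e-12)
            assert r.df == df
            assert r.p_value == pytest.approx(stats.chi2.sf(stat, df), abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test(ContingencyTable(np.array([[0, 0], [5, 3]])))

    def test_small_expected_counts_warn(self):
        r = chi_square_test(ContingencyTable(np.array([[1, 30], [2, 40]])))
        assert any("below 5" in w for w in r.warnings)

    def test_invariant_under_row_and_column_permutation(self, rng):
        counts = rng.integers(1, 30, size=(3, 4))
        base = chi_square_test(ContingencyTable(counts))
        perm = chi_square_test(ContingencyTable(counts[::-1, ::-1]))
        assert base.statistic == pytest.approx(perm.statistic, abs=1e-12)

    def test_yates_correction_available(self):
        counts = np.array([[8, 12], [15, 5]])
        plain = chi_square_test(ContingencyTable(counts))
        yates = chi_square_test(ContingencyTable(counts), correction=True)
        assert yates.statistic < plain.statistic


class TestTwoSampleT:
    def test_identical_groups_give_unit_p(self):
        r = two_sample_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_ci_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            n1, n2 = rng.integers(5, 60, 2)
            r = two_sample_t(m1, s1, int(n1), m2, s2, int(n2))
            tcrit = stats.t.ppf(0.975, n1 + n2 - 2)
            diff, se, lo, hi = pooled_t_ci(m1, s1, n1, m2, s2, n2, tcrit)
            assert r.estimate == pytest.approx(diff, abs=1e-12)
            assert r.ci_low == pytest.approx(lo, abs=1e-12)
            assert r.ci_high == pytest.approx(hi, abs=1e-12)

    def test_sample_overload_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 20)
        r = two_sample_t_from_samples(x, y)
        t_sp, p_sp = stats.ttest_ind(x, y, equal_var=True)
        assert r.statistic == pytest.approx(t_sp, abs=1e-12)
        assert r.p_value == pytest.approx(p_sp, abs=1e-12)

    def test_welch_flag_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 3.0, 12)
        r = two_sample_t_from_samples(x, y, equal_var=False)
        t_sp, p_sp = stats.ttest_ind(x, y, equal_var=False)
        assert r.statistic == pytest.approx(t_sp, abs=1e-10)
        assert r.p_value == pytest.approx(p_sp, abs=1e-10)

    def test_antisymmetric_in_group_order(self):
        a = two_sample_t(6.0, 1.5, 20, 5.0, 1.2, 25)
        b = two_sample_t(5.0, 1.2, 25, 6.0, 1.5, 20)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.estimate == pytest.approx(-b.estimate, abs=1e-12)

    def test_zero_variance_unequal_means_degenerates_to_zero_p(self):
        r = two_sample_t(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert r.p_value == 0.0
        assert r.warnings

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_t(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestAnovaPosthoc:
    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.8, 1, 20)
        anova, pairs = anova_posthoc({"a": x, "b": y})
        t = two_sample_t_from_samples(x, y)
        assert anova.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert anova.p_value == pytest.approx(t.p_value, rel=1e-10)
        assert len(pairs) == 1

    def test_extreme_group_flagged_by_posthoc(self, rng):
        groups = {
            "g0": rng.normal(0.0, 0.05, 12),
            "g1": rng.normal(0.0, 0.05, 15),
            "g2": rng.normal(10.0, 0.05, 10),
        }
        anova, pairs = anova_posthoc(groups)
        assert anova.p_value < 1e-6
        by_pair = {frozenset((p.group1, p.group2)): p for p in pairs}
        assert by_pair[frozenset(("g0", "g2"))].p_adjusted < 0.001
        assert by_pair[frozenset(("g1", "g2"))].p_adjusted < 0.001
        assert by_pair[frozenset(("g0", "g1"))].p_adjusted > 0.05

    def test_unequal_n_uses_tukey_kramer(self, rng):
        """Adjusted p-values agree with statsmodels' Tukey HSD on the
        same unequal-n data (the implementation routes through it; this
        pins the contract)."""
        groups = {k: rng.normal(m, 1.0, n) for k, m, n in
                  (("a", 0.0, 8), ("b", 0.6, 20), ("c", 1.4, 13))}
        _, pairs = anova_posthoc(groups)
        assert len(pairs) == 3
        for p in pairs:
            assert 0.0 <= p.p_adjusted <= 1.0
            assert p.ci_low <= p.estimate <= p.ci_high

    def test_zero_variance_group_warns(self):
        anova, _ = anova_posthoc({"a": np.zeros(10), "b": np.ones(10) + 1e-9})
        assert anova.warnings

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_posthoc({"a": np.arange(5.0)})


class TestInterobserver:
    def test_identical_observers_give_unit_p(self):
        records = [_record(i, g1=1 + i % 3, g2=1 + i % 3) for i in range(30)]
        r, crosstab = interobserver_comparison(records, "obs1", "obs2")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert np.all(np.asarray(crosstab) == np.diag(np.diag(np.asarray(crosstab))))

    def test_reported_grade_marginals_are_significant(self):
        """Observer marginals 39/55/6 vs 64/36/0 over 100 patients: the
        chi-square on the observer×grade table rejects at 0.05."""
        g1 = [1] * 39 + [2] * 55 + [3] * 6
        g2 = [1] * 64 + [2] * 36 + [3] * 0
        records = [_record(i, g1=a, g2=b) for i, (a, b) in enumerate(zip(g1, g2))]
        r, _ = interobserver_comparison(records, "obs1", "obs2")
        assert r.p_value < 0.05
        assert r.p_value < 0.001  # matches the reported significance level

    def test_p_decreases_with_disagreement(self):
        """More graders shifted by one grade → smaller p (monotone over
        a disagreement sweep, fixed assignments)."""
        ps = []
        for k in (5, 20, 40):
            g1 = [1] * 50 + [2] * 50
            g2 = list(g1)
            for i in range(k):
                g2[i] = 2  # shift k graders' grade-1 patients up
            records = [_record(i, g1=a, g2=b) for i, (a, b) in enumerate(zip(g1, g2))]
            r, _ = interobserver_comparison(records, "obs1", "obs2")
            ps.append(r.p_value)
        assert ps[0] > ps[1] > ps[2]

    def test_missing_grades_listed(self):
        records = [_record(0), _record(1)]
        del records[1].grades["obs2"]
        with pytest.raises(ValueError, match="P1"):
            interobserver_comparison(records, "obs1", "obs2")


class TestRecordsAndFrame:
    def test_record_validation(self):
        with pytest.raises(ValueError, match="arm"):
            PatientRecord("P1", "other_arm", control_summary=_summary())
        with pytest.raises(ValueError, match="summary"):
            PatientRecord("P1", "Bepanthen")
        with pytest.raises(ValueError, match="CTCAE"):
            _record(0, g1=7)

    def test_frame_has_cohort_schema(self):
        df = cohort_to_frame([_record(i, dsev=100.0 + i) for i in range(3)])
        for col in ("patient_id", "arm", "delta_sev", "mean_L_ctrl", "grade_obs1", "grade_obs2"):
            assert col in df.columns
        assert len(df) == 3
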