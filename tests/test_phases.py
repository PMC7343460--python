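import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agingphases import (
    ClockModel,
    OmicsMatrix,
    age_group_assignment,
    apply_linear_clock,
    association_test,
    classify_age_outliers,
    group_difference_tests,
    logistic_association,
    order_phases,
)


def series(values, prefix="S"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestOrderPhases:
    def test_relabel_by_median_age(self):
        # cluster medians 50, 30, 70, 40 -> phases 3, 1, 4, 2
        raw = series([0, 0, 1, 1, 2, 2, 3, 3])
        ages = series([49, 51, 29, 31, 69, 71, 39, 41])
        assignment = order_phases(raw, ages)
        mapping = dict(zip(raw, assignment.labels))
        assert mapping == {0: 3, 1: 1, 2: 4, 3: 2}

    def test_already_ordered_is_identity(self):
        raw = series([0, 0, 1, 1])
        ages = series([30, 32, 60, 62])
        assignment = order_phases(raw, ages)
        assert assignment.labels.tolist() == [1, 1, 2, 2]

    def test_median_tie_broken_by_mean(self):
        raw = series([0, 0, 0, 1, 1, 1])
        ages = series([40, 40, 34, 40, 40, 46])  # medians 40/40, means 38/42
        assignment = order_phases(raw, ages)
        assert assignment.labels.iloc[0] == 1  # lower-mean cluster first
        assert assignment.labels.iloc[3] == 2

    def test_missing_age_rejected(self):
        raw = series([0, 1])
        ages = pd.Series([30.0], index=["S0"])
        with pytest.raises(ValueError, match="no chronological age"):
            order_phases(raw, ages)


class TestAssociationTest:
    def test_identical_values_f_zero_p_one(self):
        values = series([5.0] * 8)
        groups = series([1, 1, 1, 1, 2, 2, 2, 2])
        stat, p = association_test(values, groups)
        assert stat == 0.0 and p == 1.0

    def test_separated_groups_tiny_p(self):
        values = series([1.0, 2.0, 3.0, 101.0, 102.0, 103.0])
        groups = series([1, 1, 1, 2, 2, 2])
        _, p = association_test(values, groups)
        assert p < 0.001
        # closed-form two-group one-way F on these numbers
        f_expected = (6 * 50.0**2 / 1) / 1.0  # MSB / MSW
        stat, _ = association_test(values, groups)
        assert stat == pytest.approx(f_expected)

    def test_kruskal_variant(self):
        values = series([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        groups = series([1, 1, 1, 2, 2, 2])
        stat, p = association_test(values, groups, method="kruskal")
        assert p < 0.1

    def test_small_group_anova_rejected(self):
        values = series([1.0, 2.0, 3.0])
        groups = series([1, 1, 2])
        with pytest.raises(ValueError, match=">= 2"):
            association_test(values, groups)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            values = series(rng.normal(size=24))
            groups = series([1] * 8 + [2] * 8 + [3] * 8)
            _, p = association_test(values, groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestLinearClock:
    def make_matrix(self, values, features):
        df = pd.DataFrame(values, index=features,
                          columns=[f"S{j}" for j in range(np.shape(values)[1])])
        return OmicsMatrix(df, kind="methylation", scale="m_value")

    def test_zero_coefficients_predict_intercept(self):
        clock = ClockModel(50.0, pd.Series({"cg1": 0.0}), "m_value")
        m = self.make_matrix([[1.0, -2.0, 3.0]], ["cg1"])
        pred = apply_linear_clock(m, clock)
        assert (pred == 50.0).all()

    def test_single_feature_arithmetic(self):
        clock = ClockModel(10.0, pd.Series({"cg1": 2.0}), "m_value")
        m = self.make_matrix([[5.0]], ["cg1"])
        assert apply_linear_clock(m, clock).iloc[0] == 20.0

    def test_missing_features_dropped_none_left_is_error(self):
        clock = ClockModel(0.0, pd.Series({"cgX": 1.0}), "m_value")
        m = self.make_matrix([[1.0]], ["cg1"])
        with pytest.raises(ValueError, match="no clock features"):
            apply_linear_clock(m, clock)

    def test_scale_mismatch_rejected(self, default_cohort):
        clock = ClockModel(0.0, pd.Series({"G00001": 1.0}), "log2_tpm")
        with pytest.raises(ValueError, match="scale"):
            apply_linear_clock(default_cohort.meth, clock)

    def test_synthetic_clock_recovers_biological_age(self, default_cohort):
        pred = apply_linear_clock(default_cohort.meth, default_cohort.clock)
        err = (pred - default_cohort.truth.bio_age).abs().median()
        assert err < 2 * default_cohort.config.bio_age_sd


class TestOutlierRule:
    def run(self, ages_by_phase):
        labels, ages = [], []
        for phase, phase_ages in ages_by_phase.items():
            labels += [phase] * len(phase_ages)
            ages += list(phase_ages)
        raw = series(labels)
        age_s = series([float(a) for a in ages])
        assignment = order_phases(raw, age_s)
        return classify_age_outliers(assignment, age_s), age_s

    def test_worked_example_type7_quantiles(self):
        # ages [30,32,34,36,38,60]: Q1=32.5, Q3=37.5, IQR=5, excess>=5/3.
        # 60 exceeds Q3 by 22.5 (young-like); 30 subceeds Q1 by 2.5,
        # which also clears the 5/3 threshold (old-like).
        out, ages = self.run({1: [30, 32, 34, 36, 38, 60]})
        assert out.stats.loc[1, "q1"] == pytest.approx(32.5)
        assert out.stats.loc[1, "q3"] == pytest.approx(37.5)
        assert (out.labels[ages == 60] == "young_like").all()
        assert (out.labels[ages == 30] == "old_like").all()
        assert (out.labels[ages.isin([32, 34, 36, 38])] == "none").all()

    def test_degenerate_equal_ages_no_outliers(self):
        out, _ = self.run({1: [40, 40, 40, 40, 40]})
        assert (out.labels == "none").all()

    def test_symmetric_ages_both_tails_flagged(self):
        # [20,30,40,50,60]: IQR=20, threshold 6.67; excess 15 on both sides
        out, ages = self.run({1: [20, 30, 40, 50, 60]})
        assert (out.labels[ages == 20] == "old_like").all()
        assert (out.labels[ages == 60] == "young_like").all()
        assert (out.labels[ages.isin([30, 40, 50])] == "none").all()

    def test_small_phase_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            self.run({1: [30, 40, 50]})

    def test_invariant_under_subject_order(self):
        ages = [30, 32, 34, 36, 38, 60]
        out1, a1 = self.run({1: ages})
        out2, a2 = self.run({1: ages[::-1]})
        merged = pd.concat(
            [out1.labels.groupby(a1).first(), out2.labels.groupby(a2).first()],
            axis=1, keys=["fwd", "rev"])
        assert (merged["fwd"] == merged["rev"]).all()


class TestGroupDifferenceTests:
    def test_identical_groups_t_zero_p_one(self):
        values = series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = series(["a"] * 3 + ["b"] * 3)
        table = group_difference_tests(values, groups, method="t_pairwise")
        row = table.iloc[0]
        assert row["statistic"] == 0.0 and row["p"] == 1.0

    def test_exact_rank_sum_enumeration(self):
        """p for {1,2,3} vs {4,5,6} equals the enumeration over all
        20 rank arrangements (2 of 20 as extreme, two-sided)."""
        pooled = [1, 2, 3, 4, 5, 6]
        observed = sum([1, 2, 3])
        extreme = 0
        arrangements = list(itertools.combinations(pooled, 3))
        for combo in arrangements:
            s = sum(combo)
            if min(s, 21 - s) <= min(observed, 21 - observed):
                extreme += 1
        p_oracle = extreme / len(arrangements)
        assert p_oracle == pytest.approx(0.1)

        values = series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = series(["a"] * 3 + ["b"] * 3)
        table = group_difference_tests(values, groups, method="wilcoxon_two_sided",
                                       adjust="none")
        assert table.iloc[0]["p"] == pytest.approx(p_oracle)

    def test_bh_adjustment_step_up(self):
        # hand-computed BH on (0.01, 0.02, 0.03) -> (0.03, 0.03, 0.03)
        values = series([0.0, 0.1, 3.0, 3.3, 7.0, 7.9, 15.0, 16.5])
        groups = series(["a", "a", "b", "b", "c", "c", "d", "d"])
        table = group_difference_tests(values, groups, method="t_pairwise")
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(table["p"], method="fdr_bh")[1]
        np.testing.assert_allclose(table["p_adjusted"], expected)
        np.testing.assert_allclose(
            multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1],
            [0.03, 0.03, 0.03])

    def test_small_group_pair_skipped_with_warning(self):
        values = series([1.0, 2.0, 3.0, 4.0, 9.0])
        groups = series(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="skipping"):
            table = group_difference_tests(values, groups, method="t_pairwise")
        assert len(table) == 1  # only (a, b) testable


class TestLogisticAssociation:
    def test_constant_outcome_rejected(self):
        y = series([1.0] * 20)
        x = series(np.arange(20.0))
        with pytest.raises(ValueError, match="constant"):
            logistic_association(y, x, age=x)

    def test_permuted_exposure_estimates_center_on_zero(self):
        rng = np.random.default_rng(1)
        coefs = []
        n = 200
        age = series(rng.uniform(20, 80, n))
        y = series((rng.random(n) < 0.4).astype(float))
        for _ in range(50):
            x = series(rng.permutation(rng.normal(size=n)))
            res = logistic_association(y, x, age=age)
            coefs.append(res.coefficient)
        assert abs(np.median(coefs)) < 0.1

    def test_too_small_sample_rejected(self):
        y = series([0.0, 1.0, 0.0, 1.0])
        x = series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="n >= 10"):
            logistic_association(y, x, age=x)


class TestAgeGroups:
    def test_quartile_bins_near_equal_sizes(self):
        ages = series(np.linspace(21, 76, 86))
        groups = age_group_assignment(ages, 4)
        counts = groups.value_counts()
        assert counts.max() - counts.min() <= 1
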