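"""The statistical battery against closed-form and simulation oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from drusenkit.synthetic import CohortParams, generate_cohort
from drusenkit.trial_stats import (
    StatConfig,
    adjusted_regression,
    chi_square_test,
    log_transform,
    oneway_anova,
    paired_t,
    pearson_corr,
    run_trial_analysis,
    two_sample_t,
    two_sample_t_summary,
)


class TestLogTransform:
    def test_values(self):
        np.testing.assert_allclose(log_transform([0.0], 1.0), [0.0])
        np.testing.assert_allclose(log_transform([np.e - 1], 1.0), [1.0])

    def test_monotone(self):
        y = np.sort(np.random.default_rng(0).uniform(0, 100, 50))
        t = log_transform(y, 1.0)
        assert (np.diff(t) >= 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform([-0.1], 1.0)


class TestStudentT:
    def test_published_age_comparison(self):
        res = two_sample_t_summary(74.4, 6.7, 87, 72.8, 6.9, 80)
        assert round(res.p, 2) == 0.13
        assert res.df == 165

    def test_identical_groups(self):
        res = two_sample_t_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_closed_form_example(self):
        res = two_sample_t_summary(1.0, 1.0, 10, 0.0, 1.0, 10)
        assert res.statistic == pytest.approx(2.236, abs=1e-3)
        assert res.df == 18
        assert res.p == pytest.approx(0.038, abs=1e-3)

    def test_raw_variant_matches_summary(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(2, 1, 15), rng.normal(1.4, 1.3, 12)
        r1 = two_sample_t(a, b)
        r2 = two_sample_t_summary(a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1), 12)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_cases(self):
        assert two_sample_t_summary(3.0, 0.0, 5, 3.0, 0.0, 5).p == 1.0
        with pytest.raises(ValueError):
            two_sample_t_summary(3.0, 0.0, 5, 4.0, 0.0, 5)
        with pytest.raises(ValueError):
            two_sample_t_summary(3.0, 1.0, 1, 4.0, 1.0, 5)

    def test_scale_invariance_of_p(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        assert two_sample_t(a, b).p == pytest.approx(two_sample_t(7 * a + 3, 7 * b + 3).p)


class TestChiSquare:
    def test_published_gender_table(self):
        res = chi_square_test([[28, 59], [36, 44]])
        assert round(res.p, 2) == 0.09

    def test_independent_table(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_diagonal_table_closed_form(self):
        res = chi_square_test([[5, 0], [0, 5]])
        assert res.statistic == pytest.approx(10.0)
        assert res.df == 1
        assert res.p == pytest.approx(0.00157, abs=5e-5)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [3, 4]])

    def test_statistic_matches_hand_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            obs = rng.integers(1, 20, (2, 3)).astype(float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            hand = ((obs - exp) ** 2 / exp).sum()
            assert chi_square_test(obs).statistic == pytest.approx(hand)

    def test_permutation_oracle_orders_tables_consistently(self):
        """Exhaustive label permutation on tiny tables ranks association the
        same way the asymptotic chi-square p does (exact agreement is not
        expected at n ≤ 12 where the permutation law is discrete)."""
        from itertools import combinations

        def perm_p(table):
            table = np.asarray(table)
            n1 = table[0].sum()
            n = table.sum()
            k = table[:, 0].sum()  # successes overall
            obs_stat = chi_square_test(table).statistic
            count = tot = 0
            for chosen in combinations(range(int(n)), int(n1)):
                k1 = sum(1 for i in chosen if i < k)
                t = np.array([[k1, n1 - k1], [k - k1, n - n1 - (k - k1)]], float)
                if (t.sum(0) > 0).all() and (t.sum(1) > 0).all():
                    s = ((t - np.outer(t.sum(1), t.sum(0)) / n) ** 2 /
                         (np.outer(t.sum(1), t.sum(0)) / n)).sum()
                    tot += 1
                    count += s >= obs_stat - 1e-9
            return count / tot

        tables = [[[5, 1], [2, 4]], [[3, 3], [3, 3]], [[5, 0], [0, 5]]]
        asym = [chi_square_test(t).p for t in tables]
        exact = [perm_p(t) for t in tables]
        assert np.argsort(asym).tolist() == np.argsort(exact).tolist()


class TestPairedT:
    def test_identical_columns(self):
        v = np.array([1.0, 2.0, 3.0])
        res = paired_t(v, v)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_closed_form_df2(self):
        # log-scale differences (1, 0, 2): t = √3, p = 1 − t/√(2+t²) ≈ 0.225
        baseline = np.zeros(3)
        final = np.array([np.e - 1, 0.0, np.exp(2) - 1])
        res = paired_t(baseline, final, c=1.0)
        assert res.statistic == pytest.approx(np.sqrt(3))
        t = np.sqrt(3)
        assert res.p == pytest.approx(1 - t / np.sqrt(2 + t * t), abs=1e-9)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 50, 12)
        fin = rng.uniform(1, 50, 12)
        fwd = paired_t(base, fin)
        rev = paired_t(fin, base)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p == pytest.approx(rev.p)

    def test_zero_variance_nonzero_mean_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestAdjustedRegression:
    def test_constant_outcome(self):
        rng = np.random.default_rng(5)
        n = 40
        res = adjusted_regression(
            np.full(n, 3.0),
            rng.integers(0, 2, n),
            rng.normal(70, 5, n),
            rng.integers(0, 2, n),
        )
        assert res.estimate == pytest.approx(0.0, abs=1e-10)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_noiseless_construction_recovered_exactly(self):
        rng = np.random.default_rng(6)
        n = 60
        arm = rng.integers(0, 2, n).astype(float)
        age = rng.normal(70, 6, n)
        gender = rng.integers(0, 2, n).astype(float)
        y = 3.0 * arm + 0.5 * age - 2.0 * gender
        res = adjusted_regression(y, arm, age, gender)
        assert res.estimate == pytest.approx(3.0, abs=1e-9)

    def test_balanced_design_equals_raw_difference(self):
        # identical age/gender composition in both arms: adjustment is inert
        age = np.tile(np.array([60.0, 65.0, 70.0, 75.0]), 2)
        gender = np.tile(np.array([0.0, 1.0, 0.0, 1.0]), 2)
        arm = np.repeat([1.0, 0.0], 4)
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 8)
        res = adjusted_regression(y, arm, age, gender)
        raw = y[arm == 1].mean() - y[arm == 0].mean()
        assert res.estimate == pytest.approx(raw, abs=1e-9)

    def test_rank_deficiency_named(self):
        n = 30
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="arm"):
            adjusted_regression(
                rng.normal(0, 1, n), np.ones(n), rng.normal(70, 5, n),
                rng.integers(0, 2, n),
            )

    def test_null_coverage(self):
        rng = np.random.default_rng(9)
        n, reps, covered = 167, 400, 0
        for _ in range(reps):
            arm = (rng.random(n) < 0.5).astype(float)
            age = rng.normal(73, 7, n)
            gender = (rng.random(n) < 0.6).astype(float)
            y = 0.1 * age + rng.normal(0, 1, n)  # no arm effect
            res = adjusted_regression(y, arm, age, gender)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.03)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_corr(x, x).estimate == pytest.approx(1.0)
        assert pearson_corr(x, -x).estimate == pytest.approx(-1.0)

    def test_hand_example(self):
        res = pearson_corr([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert res.estimate == pytest.approx(0.9820, abs=5e-5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_matches_t_formula(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        res = pearson_corr(x, y)
        t = res.estimate * np.sqrt(23 / (1 - res.estimate**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 23))


class TestAnova:
    def test_identical_groups(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        res = oneway_anova(v, g)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_closed_form_f3(self):
        v = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], float)
        g = np.repeat(["a", "b", "c"], 3)
        res = oneway_anova(v, g)
        assert res.statistic == pytest.approx(3.0)
        assert res.df == (2, 6)
        assert res.p == pytest.approx(0.125)  # (1 + F/3)^-3 at F=3

    def test_null_p_uniform_under_permutation(self):
        rng = np.random.default_rng(11)
        v = rng.normal(0, 1, 30)
        g = np.repeat(["a", "b", "c"], 10)
        ps = []
        for _ in range(300):
            ps.append(oneway_anova(v, rng.permutation(g)).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_variance(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestRunTrialAnalysis:
    def test_report_structure(self):
        cohort = generate_cohort(CohortParams(n=120, seed=12))
        report = run_trial_analysis(cohort, StatConfig())
        assert len(report["adjusted"]) == 12  # 3 metrics × 4 fields
        assert len(report["covariates"]) == 12
        assert set(report["adjusted"]["metric"]) == {"number", "diameter", "area"}
        assert set(report["adjusted"]["field"]) == {"inner", "middle", "outer", "all"}
        assert report["adjusted"]["p"].between(0, 1).all()

    def test_threshold_changes_flags_not_pvalues(self):
        cohort = generate_cohort(CohortParams(n=120, seed=13))
        r1 = run_trial_analysis(cohort, StatConfig(bonferroni_threshold=0.005))
        r2 = run_trial_analysis(cohort, StatConfig(bonferroni_threshold=0.5))
        np.testing.assert_allclose(r1["adjusted"]["p"], r2["adjusted"]["p"])
        assert r2["adjusted"]["significant"].sum() >= r1["adjusted"]["significant"].sum()

    def test_single_arm_cohort_contract(self):
        cohort = generate_cohort(CohortParams(n=60, seed=14))
        cohort["arm"] = "treated"
        report = run_trial_analysis(cohort, StatConfig())
        assert report["adjusted"] is None
        assert len(report["paired"]) == 12
        assert len(report["covariates"]) == 12
        assert any("arm" in e for e in report["errors"])

    def test_empty_cohort_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            run_trial_analysis(pd.DataFrame(), StatConfig())
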