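import numpy as np
import pytest
from scipy import stats as st

from impulsed.cohort_stats import (build_reports, compare_groups,
                                   icc_reliability, logistic_combination,
                                   roc_analysis, summarize_cohort)


def brute_force_auc(scores, labels):
    """Pairwise concordance oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCompareGroups:
    def test_identical_groups(self):
        gc = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert gc.t_stat == 0.0
        assert gc.p_value == 1.0

    def test_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        g1 = compare_groups(a, b)
        g2 = compare_groups(a * 7.3, b * 7.3)
        assert g1.t_stat == pytest.approx(g2.t_stat, rel=1e-9)
        assert g1.p_value == pytest.approx(g2.p_value, rel=1e-9)

    def test_zero_variance_convention(self):
        gc = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0])
        assert gc.p_value == 1.0 and gc.flagged
        gc2 = compare_groups([2.0, 2.0], [3.0, 3.0])
        assert gc2.p_value == 0.0 and gc2.flagged

    def test_power_matches_closed_form(self):
        """Rejection rate over 1000 replicates within 3 SE of nct power."""
        rng = np.random.default_rng(3)
        n, reps = 50, 1000
        rej = sum(compare_groups(rng.normal(0, 1, n),
                                 rng.normal(1, 1, n)).p_value < 0.05
                  for _ in range(reps))
        df = 2 * n - 2
        tcrit = st.t.ppf(0.975, df)
        ncp = 1.0 / np.sqrt(2.0 / n)
        power = 1 - st.nct.cdf(tcrit, df, ncp) + st.nct.cdf(-tcrit, df, ncp)
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(rej / reps - power) < 3 * se

    def test_welch_switch_on_levene(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 6, 40)
        gc = compare_groups(a, b)
        assert gc.levene_p < 0.05
        assert not gc.equal_var

    def test_stars(self, rng):
        gc = compare_groups(rng.normal(0, 1, 60), rng.normal(3, 1, 60))
        assert gc.stars == "***"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestRocAnalysis:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12.0],
                         [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 100.0 and r.specificity == 100.0

    def test_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(8, 40)
            scores = np.round(rng.normal(0, 1, n), 1)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = roc_analysis(scores, labels)
            bf = brute_force_auc(scores, labels)
            assert r.auc == pytest.approx(max(bf, 1 - bf), abs=1e-12)

    def test_label_inversion_flips_raw_auc(self, rng):
        from impulsed.cohort_stats import _auc_mannwhitney
        scores = rng.normal(0, 1, 50)
        labels = rng.random(50) < 0.4
        a1 = _auc_mannwhitney(scores, labels)
        a2 = _auc_mannwhitney(scores, ~labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(2, 1, 60)
        labels = rng.random(60) < 0.5
        r1 = roc_analysis(scores, labels)
        r2 = roc_analysis(np.exp(scores), labels)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_orientation_flag(self):
        # marker lower in positives -> inverted orientation, auc >= 0.5
        r = roc_analysis([10, 11, 12, 1, 2, 3.0], [0, 0, 0, 1, 1, 1])
        assert not r.higher_is_positive
        assert r.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_analysis([1.0, 2.0], [1, 1])


class TestLogisticCombination:
    def test_single_feature_auc_unchanged(self, rng):
        x = rng.normal(0, 1, 80)
        y = (x + rng.normal(0, 1, 80)) > 0
        _, comb, _ = logistic_combination(x[:, None], y)
        single = roc_analysis(x, y)
        assert comb.auc == pytest.approx(single.auc, abs=1e-12)

    def test_likelihood_never_decreases_with_noise_feature(self):
        """Nested-model guarantee checked on the actual ML objective."""
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (100, 1))
        y = (X[:, 0] + rng.normal(0, 1, 100)) > 0
        noise = rng.normal(0, 1, (100, 1))

        def loglik(scores, y):
            p = 1.0 / (1.0 + np.exp(-scores))
            return np.sum(np.log(np.where(y, p, 1 - p)))

        s1, r1, _ = logistic_combination(X, y)
        s2, r2, _ = logistic_combination(np.hstack([X, noise]), y)
        assert loglik(s2, y) >= loglik(s1, y) - 1e-9
        # in-sample AUC does not drop at this fixed seed either
        assert r2.auc >= r1.auc - 1e-12

    def test_separation_triggers_ridge_fallback(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        _, roc, flagged = logistic_combination(X, y)
        assert flagged
        assert roc.auc == 1.0

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            logistic_combination(X, [0, 1, 0])


class TestIccReliability:
    def test_identical_ratings(self, rng):
        r = rng.normal(0, 1, 30)
        icc = icc_reliability(r, r)
        assert icc.icc == 1.0

    def test_null_ratings_near_zero(self):
        rng = np.random.default_rng(8)
        icc = icc_reliability(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
        assert -0.2 < icc.icc < 0.2

    def test_calibrated_range(self, rng):
        truth = rng.normal(10, 2, 100)
        noise_sd = truth.std(ddof=1) * np.sqrt(0.2)
        r1 = truth + rng.normal(0, noise_sd, 100)
        r2 = truth + rng.normal(0, noise_sd, 100)
        icc = icc_reliability(r1, r2)
        assert 0.75 <= icc.icc <= 0.95
        assert icc.ci_low <= icc.icc <= icc.ci_high

    def test_constant_ratings_flagged(self):
        icc = icc_reliability([1.0] * 10, [1.0] * 10)
        assert icc.flagged

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            icc_reliability([1.0, 2.0], [1.0, 2.0])


class TestSummarizeCohort:
    def test_printed_percentages(self, default_cohort):
        s = summarize_cohort(default_cohort)
        assert s["er_pos_pct"] == 74.36
        assert s["pr_pos_pct"] == 62.39
        assert s["her2_pos_pct"] == 39.32
        assert s["ki67_high_pct"] == 88.89
        assert s["grade_II_pct"] == 57.26
        assert s["subtype_LuminalB_pct"] == 60.68

    def test_exhaustive_percentages_sum_to_100(self, default_cohort):
        s = summarize_cohort(default_cohort)
        grade_total = sum(s[f"grade_{g}_pct"] for g in ("I", "II", "III"))
        assert grade_total == pytest.approx(100.0, abs=0.05)
        sub_total = sum(s[f"subtype_{t}_pct"]
                        for t in ("LuminalA", "LuminalB", "HER2over", "TN"))
        assert sub_total == pytest.approx(100.0, abs=0.05)

    def test_empty_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame())


@pytest.fixture(scope="module")
def reports(default_cohort):
    return build_reports(default_cohort)


class TestBuildReports:
    def test_comparison_row_count(self, reports):
        table4, _ = reports
        # 6 contrasts x 8 parameters
        assert len(table4) == 48

    def test_null_grade_contrast_not_significant(self, reports):
        table4, _ = reports
        grade = table4[table4.contrast == "grade_I-II_vs_III"]
        assert (grade["p_value"] >= 0.05).all()

    def test_benign_malignant_directions(self, reports):
        table4, _ = reports
        bm = table4[table4.contrast == "benign_vs_malignant"].set_index(
            "parameter")
        for p in ("d_mean", "f_in", "cellularity"):
            assert bm.loc[p, "mean_pos"] > bm.loc[p, "mean_neg"]
        for p in ("D_ex", "ADC_DWI", "ADC_PGSE", "ADC_17Hz", "ADC_33Hz"):
            assert bm.loc[p, "mean_pos"] < bm.loc[p, "mean_neg"]

    def test_combinations_present(self, reports):
        _, table5 = reports
        assert {"Comb1", "Comb2"} <= set(
            table5[table5.contrast == "benign_vs_malignant"]["marker"])

    def test_bh_column_monotone_vs_raw(self, reports):
        table4, _ = reports
        assert (table4["p_bh"] >= table4["p_value"] - 1e-12).all()

    def test_reports_byte_stable(self, default_cohort):
        t4a, t5a = build_reports(default_cohort)
        t4b, t5b = build_reports(default_cohort)
        assert t4a.to_csv(index=False) == t4b.to_csv(index=False)
        assert t5a.to_csv(index=False) == t5b.to_csv(index=False)

    def test_permutation_destroys_significance(self, default_cohort):
        rng = np.random.default_rng(9)
        vals = default_cohort["ADC_DWI"].to_numpy()
        is_mal = (default_cohort["group"] == "malignant").to_numpy()
        ps = []
        for _ in range(50):
            perm = rng.permutation(is_mal)
            ps.append(compare_groups(vals[perm], vals[~perm]).p_value)
        assert np.median(ps) > 0.3

    def test_empty_arm_skipped_with_warning(self, default_cohort):
        crippled = default_cohort[default_cohort["grade"] != "III"]
        with pytest.warns(UserWarning, match="grade"):
            build_reports(crippled)
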