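import numpy as np
import pandas as pd
import pytest

from impulsed.signal_model import PARAM_BOUNDS, TissueParams
from impulsed.synthetic_cohort import (CohortSpec, apply_exclusions,
                                       check_subtype_feasibility, cohort_table,
                                       draw_tissue_params,
                                       generate_lesion_image, generate_roster,
                                       roster_table, simulate_observer_pair,
                                       subtype_from_markers)


class TestRosterGeneration:
    def test_default_enrollment_counts(self, default_spec):
        roster = generate_roster(default_spec, seed=17)
        assert len(roster) == 236
        enrolled, report = apply_exclusions(roster)
        assert len(enrolled) == 213
        assert report == {"small_lesion": 10, "no_pathology": 5,
                          "poor_quality": 8}

    def test_exclusion_reasons_disjoint(self, default_spec):
        roster = generate_roster(default_spec, seed=3)
        for rec in roster:
            n_failing = sum([rec.lesion_diameter_mm < 8,
                             not rec.pathology_available,
                             not rec.image_quality_ok])
            assert n_failing == (0 if rec.enrolled else 1)

    def test_zero_exclusions_all_enrolled(self):
        spec = CohortSpec(n_collected=213,
                          exclusions={"small_lesion": 0, "no_pathology": 0,
                                      "poor_quality": 0})
        roster = generate_roster(spec, seed=1)
        enrolled, report = apply_exclusions(roster)
        assert len(enrolled) == 213
        assert sum(report.values()) == 0

    def test_empty_roster(self):
        cohort, report = apply_exclusions([])
        assert cohort == [] and sum(report.values()) == 0

    def test_determinism_same_seed(self, default_spec):
        r1 = roster_table(generate_roster(default_spec, seed=5))
        r2 = roster_table(generate_roster(default_spec, seed=5))
        pd.testing.assert_frame_equal(r1, r2)

    def test_different_seed_same_marginals(self, default_spec):
        r1 = roster_table(generate_roster(default_spec, seed=5))
        r2 = roster_table(generate_roster(default_spec, seed=6))
        assert not r1.equals(r2)
        for col in ("group", "er", "grade", "subtype"):
            pd.testing.assert_series_equal(
                r1[col].value_counts(), r2[col].value_counts())

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_collected=10).validate()

    def test_from_yaml_default_matches(self, default_spec):
        assert CohortSpec.from_yaml() == default_spec


@pytest.fixture(scope="module")
def cohort(default_spec):
    enrolled, _ = apply_exclusions(generate_roster(default_spec, seed=17))
    return cohort_table(enrolled)


class TestComposition:
    def test_group_split(self, cohort):
        assert (cohort["group"] == "benign").sum() == 83
        assert (cohort["group"] == "malignant").sum() == 130

    def test_ibc_count(self, cohort):
        assert cohort["is_ibc"].sum() == 117

    def test_ihc_marginals(self, cohort):
        ibc = cohort[cohort["is_ibc"]]
        assert (ibc["er"] == "pos").sum() == 87
        assert (ibc["pr"] == "pos").sum() == 73
        assert (ibc["her2"] == "pos").sum() == 46
        assert (ibc["ki67"] == "high").sum() == 104

    def test_grades_and_subtypes(self, cohort):
        ibc = cohort[cohort["is_ibc"]]
        assert ibc["grade"].value_counts().to_dict() == {"II": 67, "III": 46,
                                                         "I": 4}
        assert ibc["subtype"].value_counts().to_dict() == {
            "LuminalB": 71, "HER2over": 26, "TN": 12, "LuminalA": 8}

    def test_ihc_only_on_ibc(self, cohort):
        non_ibc = cohort[~cohort["is_ibc"]]
        assert non_ibc["er"].isna().all()
        assert non_ibc["subtype"].isna().all()


class TestSubtypeRules:
    def test_rule_mapping(self):
        assert subtype_from_markers(True, False, False) == "LuminalA"
        assert subtype_from_markers(False, True, True) == "LuminalB"
        assert subtype_from_markers(False, False, True) == "HER2over"
        assert subtype_from_markers(False, False, False) == "TN"

    def test_default_spec_reports_infeasibility(self, default_spec):
        feas = check_subtype_feasibility(default_spec)
        assert not feas["feasible"]
        assert feas["min_inconsistent"] == 51  # (71 + 26) - 46

    def test_consistency_flags_present(self, default_spec):
        enrolled, _ = apply_exclusions(generate_roster(default_spec, seed=17))
        tab = cohort_table(enrolled)
        flags = tab.loc[tab["is_ibc"], "subtype_rule_consistent"]
        assert flags.notna().all()


class TestTissueDraws:
    def test_malignant_mean_matches_target(self, default_spec):
        rng = np.random.default_rng(0)
        d = [draw_tissue_params(default_spec, "malignant", rng).d_mean
             for _ in range(10_000)]
        se = 2.677 / np.sqrt(10_000)
        assert abs(np.mean(d) - 15.74) < 2 * se

    def test_sd_zero_draws_equal_mean(self):
        spec = CohortSpec(param_distributions={
            "benign": {"d_mean": (14.0, 0.0), "f_in": (0.3, 0.0),
                       "D_ex": (2.0, 0.0)},
            "malignant": {"d_mean": (16.0, 0.0), "f_in": (0.35, 0.0),
                          "D_ex": (2.1, 0.0)}})
        rng = np.random.default_rng(1)
        draws = [draw_tissue_params(spec, "benign", rng) for _ in range(5)]
        assert all(p.d_mean == 14.0 and p.f_in == 0.3 and p.D_ex == 2.0
                   for p in draws)

    def test_draws_respect_bounds(self, default_spec):
        rng = np.random.default_rng(2)
        for _ in range(2000):
            p = draw_tissue_params(default_spec, "benign", rng)
            assert 4 < p.d_mean < 30
            assert 0 < p.f_in < 1
            assert 0 < p.D_ex < 3.5

    def test_fd_draws_correlated(self, default_spec):
        rng = np.random.default_rng(3)
        ps = [draw_tissue_params(default_spec, "malignant", rng)
              for _ in range(4000)]
        r = np.corrcoef([p.d_mean for p in ps], [p.f_in for p in ps])[0, 1]
        assert r == pytest.approx(default_spec.fd_correlation, abs=0.05)

    def test_unknown_stratum(self, default_spec):
        with pytest.raises(ValueError, match="stratum"):
            draw_tissue_params(default_spec, "intermediate", 0)


class TestLesionPhantom:
    def test_noiseless_equals_forward_model(self, model):
        truth = TissueParams(15.0, 0.4, 2.0)
        ph = generate_lesion_image(truth, model, shape=(6, 6, 1), snr=np.inf,
                                   seed=0, jitter_cv=0.0)
        shells = model.protocol.shells()
        expected = model.predict(truth.d_mean, truth.f_in, truth.D_ex, shells)
        for ijk in np.argwhere(ph.mask):
            np.testing.assert_allclose(ph.volume4d[tuple(ijk)], expected)
        assert np.all(ph.volume4d[~ph.mask] == 0.0)

    def test_rayleigh_noise_floor(self, model):
        """Background (S=0) magnitude mean -> sigma * sqrt(pi/2)."""
        snr = 50.0
        ph = generate_lesion_image(TissueParams(15.0, 0.4, 2.0), model,
                                   shape=(12, 12, 3), snr=snr, seed=4)
        bg = ph.volume4d[~ph.mask]
        expected = np.sqrt(np.pi / 2.0) / snr
        assert bg.mean() == pytest.approx(expected, rel=0.03)

    def test_jitter_respects_bounds(self, model):
        ph = generate_lesion_image(TissueParams(29.0, 0.95, 3.4), model,
                                   shape=(8, 8, 1), snr=np.inf, seed=5,
                                   jitter_cv=0.3)
        lo, hi = PARAM_BOUNDS["d_mean"]
        d = ph.truth_maps["d_mean"][ph.mask]
        assert np.all((d > lo) & (d < hi))

    def test_invalid_snr(self, model):
        with pytest.raises(ValueError, match="snr"):
            generate_lesion_image(TissueParams(15.0, 0.4, 2.0), model,
                                  snr=0.0)

    def test_mask_shape_mismatch(self, model):
        with pytest.raises(ValueError, match="mask shape"):
            generate_lesion_image(TissueParams(15.0, 0.4, 2.0), model,
                                  shape=(6, 6, 1),
                                  mask=np.ones((3, 3, 1), dtype=bool))


class TestObserverSimulation:
    def test_icc_lands_in_calibrated_range(self, rng):
        from impulsed.cohort_stats import icc_reliability
        values = rng.normal(15.0, 3.0, 213)
        r1, r2 = simulate_observer_pair(values, seed=2)
        icc = icc_reliability(r1, r2)
        assert 0.75 <= icc.icc <= 0.95


class TestCohortTable:
    def test_adc_direction_malignant_lower(self, default_cohort):
        mal = default_cohort[default_cohort.group == "malignant"]
        ben = default_cohort[default_cohort.group == "benign"]
        for col in ("ADC_DWI", "ADC_PGSE", "ADC_17Hz", "ADC_33Hz"):
            assert mal[col].mean() < ben[col].mean()

    def test_expected_columns(self, default_cohort):
        for col in ("group", "is_ibc", "d_mean", "f_in", "D_ex",
                    "cellularity", "ADC_DWI", "ADC_33Hz"):
            assert col in default_cohort.columns
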