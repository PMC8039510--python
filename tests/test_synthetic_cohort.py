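import numpy as np
import pandas as pd
import pytest

from popmm.minimal_model import TestType, simulate_glucose
from popmm.population_model import reference_base_population
from popmm.synthetic_cohort import (
    CohortSpec,
    ImputationRules,
    TruncNormSpec,
    generate_covariates,
    impute_missing,
    insulin_profile,
    sampling_schedule,
    simulate_trial,
)


class TestCovariateGeneration:
    @pytest.fixture(scope="class")
    def big_table(self):
        spec = CohortSpec(n_subjects=5000, seed=1)
        return spec, generate_covariates(spec, np.random.default_rng(1))

    def test_marginal_means_match_targets(self, big_table):
        spec, tab = big_table
        n = len(tab)
        for col, tspec in (("age_yr", spec.age), ("height_cm", spec.height),
                           ("bmi_kg_m2", spec.bmi)):
            se = tab[col].std() / np.sqrt(n)
            assert abs(tab[col].mean() - tspec.mean) < 3 * se, col
            assert tab[col].min() >= tspec.lower
            assert tab[col].max() <= tspec.upper

    def test_cohort_fraction_binomial(self, big_table):
        spec, tab = big_table
        frac = (tab.cohort == "T2D").mean()
        se = np.sqrt(spec.frac_T2D * (1 - spec.frac_T2D) / len(tab))
        assert abs(frac - spec.frac_T2D) < 3 * se

    def test_bmi_weight_height_consistent(self, big_table):
        _, tab = big_table
        np.testing.assert_allclose(
            tab.weight_kg, tab.bmi_kg_m2 * (tab.height_cm / 100) ** 2,
            rtol=1e-12)

    def test_seeded_determinism(self):
        spec = CohortSpec(n_subjects=50, seed=3)
        a = generate_covariates(spec, np.random.default_rng(3))
        b = generate_covariates(spec, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValueError):
            TruncNormSpec(50.0, 5.0, 60.0, 70.0)


class TestImputation:
    def _table(self, **overrides):
        base = {"subject_id": ["a", "b", "c", "d"],
                "age_yr": [30.0, 40.0, 50.0, 60.0],
                "weight_kg": [70.0, 80.0, 90.0, 60.0],
                "height_cm": [170.0, 175.0, 180.0, 160.0],
                "bmi_kg_m2": [24.2, 26.1, 27.8, 23.4],
                "sex": ["F", "M", "F", "M"]}
        base.update(overrides)
        return pd.DataFrame(base)

    def test_fully_observed_unchanged(self):
        t = self._table()
        out = impute_missing(t, ImputationRules(), np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, t)

    def test_mean_assignment_for_missing_age(self):
        t = self._table(age_yr=[30.0, np.nan, 50.0, np.nan])
        out = impute_missing(t, ImputationRules(), np.random.default_rng(0))
        assert out.age_yr.iloc[1] == pytest.approx(40.0)

    def test_sex_assignment_follows_proportions(self):
        rng = np.random.default_rng(5)
        counts = {"F": 0, "M": 0}
        for _ in range(50):
            t = self._table(sex=["F", None, None, "M"])
            out = impute_missing(t, ImputationRules((0.5, 0.5)), rng)
            for s in out.sex.iloc[1:3]:
                counts[s] += 1
        assert 20 < counts["F"] < 80  # 100 draws at p=0.5

    def test_popgen_surrogate_height_weight_from_bmi(self):
        t = self._table(weight_kg=[np.nan, 80.0, 90.0, 60.0],
                        height_cm=[np.nan, 175.0, 180.0, 160.0])
        out = impute_missing(t, ImputationRules(), np.random.default_rng(2))
        h, w, b = (out.iloc[0][c] for c in ("height_cm", "weight_kg",
                                            "bmi_kg_m2"))
        assert 140 < h < 185
        assert w == pytest.approx(b * (h / 100) ** 2, rel=1e-9)

    def test_height_from_weight_and_mean_bmi(self):
        t = self._table(height_cm=[np.nan, 175.0, 180.0, 160.0],
                        bmi_kg_m2=[np.nan, 26.1, 27.8, 23.4])
        out = impute_missing(t, ImputationRules(), np.random.default_rng(2))
        mean_bmi = np.mean([26.1, 27.8, 23.4])
        assert out.height_cm.iloc[0] == pytest.approx(
            100 * np.sqrt(70.0 / mean_bmi))

    def test_unimputable_gap_raises(self):
        t = self._table(weight_kg=[np.nan] * 4, height_cm=[np.nan] * 4,
                        bmi_kg_m2=[np.nan] * 4)
        with pytest.raises(ValueError):
            impute_missing(t, ImputationRules(), np.random.default_rng(0))


class TestInsulinProfile:
    COV_ND = {"t2d": 0.0, "weight_kg": 75.0, "cohort": "ND"}

    def test_starts_at_basal(self):
        f = insulin_profile(self.COV_ND, TestType.IVGTT,
                            np.random.default_rng(1), 180.0)
        assert f.concentrations[0] == pytest.approx(f.Ibasal)

    def test_im_identical_before_20min(self):
        a = insulin_profile(self.COV_ND, TestType.IVGTT,
                            np.random.default_rng(9), 200.0)
        b = insulin_profile(self.COV_ND, TestType.IM_IVGTT,
                            np.random.default_rng(9), 200.0)
        np.testing.assert_array_equal(a.times, b.times)
        pre = a.times <= 20.0
        np.testing.assert_allclose(b.concentrations[pre],
                                   a.concentrations[pre], rtol=1e-12)
        assert np.any(b.concentrations[~pre] > a.concentrations[~pre])

    def test_returns_to_basal_and_floor(self):
        for seed in range(5):
            f = insulin_profile(self.COV_ND, TestType.IM_IVGTT,
                                np.random.default_rng(seed), 240.0)
            assert f.concentrations[-1] == pytest.approx(f.Ibasal, rel=0.10)
            assert np.all(f.concentrations >= f.Ibasal / 2)

    def test_t2d_has_blunted_first_phase(self):
        # compare the early (first-phase) excursion relative to basal
        ratios = {"ND": [], "T2D": []}
        for seed in range(20):
            for cohort in ("ND", "T2D"):
                cov = {"t2d": float(cohort == "T2D"), "cohort": cohort}
                f = insulin_profile(cov, TestType.IVGTT,
                                    np.random.default_rng(seed), 180.0)
                early = f.times <= 15.0
                ratios[cohort].append(
                    f.concentrations[early].max() / f.Ibasal)
        assert np.median(ratios["ND"]) > np.median(ratios["T2D"])


class TestSamplingSchedule:
    @pytest.mark.parametrize("test_type,nmax,dmax", [
        (TestType.IVGTT, 30, 360.0), (TestType.IM_IVGTT, 22, 240.0)])
    def test_published_design_ranges(self, test_type, nmax, dmax):
        for seed in range(30):
            t = sampling_schedule(test_type, np.random.default_rng(seed))
            assert 12 <= t.size <= nmax
            assert 180.0 <= t[-1] <= dmax
            assert t[0] == 0.0
            assert np.all(np.diff(t) > 0)
            # dense early sampling
            assert (t <= 30).sum() >= 5


class TestTrialSimulation:
    def test_zero_noise_reproduces_predictions(self):
        base = reference_base_population()
        from popmm.population_model import PopulationParams
        pop = PopulationParams(base.mu_logtheta, base.Sigma_logtheta,
                               sigma_prop=1e-12)
        spec = CohortSpec(n_subjects=5, true_pop=pop, basal_noise_cv=1e-12,
                          seed=2)
        trial = simulate_trial(spec)
        for s in trial.subjects:
            pred = simulate_glucose(trial.truth[s.subject_id], s.dose,
                                    s.Gbasal, s.Ibasal, s.forcing, s.obs_times)
            np.testing.assert_allclose(s.obs_glucose, pred, rtol=1e-6)

    def test_noise_cv_matches_sigma(self):
        spec = CohortSpec(n_subjects=150, seed=4,
                          true_pop=reference_base_population())
        trial = simulate_trial(spec)
        resid = []
        for s in trial.subjects:
            pred = simulate_glucose(trial.truth[s.subject_id], s.dose,
                                    s.Gbasal * 1.0, s.Ibasal, s.forcing,
                                    s.obs_times)
            # Gbasal carries measurement noise; regenerate with observed one
            resid.extend(((s.obs_glucose - pred) / pred).tolist())
        cv = np.std(resid)
        assert cv == pytest.approx(0.0706, rel=0.15)

    def test_determinism_and_no_truth_leakage(self, small_trial):
        spec = CohortSpec(n_subjects=12,
                          true_pop=reference_base_population(), seed=7)
        again = simulate_trial(spec)
        for a, b in zip(small_trial.subjects, again.subjects):
            np.testing.assert_array_equal(a.obs_glucose, b.obs_glucose)
            np.testing.assert_array_equal(a.forcing.concentrations,
                                          b.forcing.concentrations)
        assert "true_GEZI" not in small_trial.covariate_table.columns
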