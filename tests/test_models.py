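"""Attendance models: diagnostics, repeatability, Cramer's V, suite,
model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from roostkit.glmm import GLMMFit, RandomTerm, fit_glmm
from roostkit.models import (
    AttendanceFit,
    ModelSpec,
    adjusted_repeatability,
    binned_residuals,
    classification_accuracy,
    compare_models,
    cramers_v,
    fit_attendance_model,
    latent_repeatability,
    original_scale_age_coefficients,
    plasticity_mortality_suite,
    predict_attendance,
    variance_inflation_factors,
)
from roostkit.synthetic import (
    AttendanceTruth,
    PopulationConfig,
    make_fixture,
    simulate_mortality_scenario,
    truth_interval_units,
)

TRUTH = AttendanceTruth()


@pytest.fixture(scope="module")
def juvenile_fit():
    cfg = PopulationConfig(n_juvenile_tagged=100, n_adult_tagged=0,
                           n_winters=5, seed=13)
    pop, _, tt = make_fixture(cfg, TRUTH)
    units = truth_interval_units(tt, pop)
    spec = ModelSpec.juvenile(age_center=TRUTH.age_center,
                              age_scale=TRUTH.age_scale)
    return fit_attendance_model(units, spec), units


class TestModelSpec:
    def test_adult_spec_excludes_age_and_breeding(self):
        with pytest.raises(ValueError):
            ModelSpec(cohort="adult", fixed=("age", "sex"))
        assert ModelSpec.adult().fixed == ("sex",)

    def test_needs_two_birds_two_winters(self):
        units = pd.DataFrame(dict(
            bird_id=["a"] * 4, winter_id=[2016] * 4,
            interval_index=[1, 2, 3, 4], attendance=[0, 1, 0, 1],
            age=[2.0] * 4, sex=["f"] * 4, breeding_status=[0] * 4,
            weight=[1.0] * 4, tag_class=["juvenile"] * 4))
        with pytest.raises(ValueError):
            fit_attendance_model(units)


class TestFitAndPredict:
    def test_fit_recovers_signs(self, juvenile_fit):
        fit, _ = juvenile_fit
        s = fit.summary.set_index("term")
        assert s.loc["sex_male", "lower"] > 0      # males attend more
        assert s.loc["age2", "estimate"] < 0       # concave age profile
        assert fit.converged

    def test_back_transform_consistency(self, juvenile_fit):
        fit, _ = juvenile_fit
        orig = original_scale_age_coefficients(fit)
        s = fit.summary.set_index("term")
        c1, c2 = s.loc["age", "estimate"], s.loc["age2", "estimate"]
        m, sc = fit.age_center, fit.age_scale
        for a in (1.0, 4.0):
            z = (a - m) / sc
            lhs = c1 * z + c2 * z**2
            rhs = orig["age"] * a + orig["age2"] * a**2 \
                + (c2 * m**2 / sc**2 - c1 * m / sc)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_plugin_prediction_matches_inverse_logit(self):
        beta = np.array([-0.4, 1.0])
        glmm = GLMMFit(
            beta=beta, se_beta=np.zeros(2), vcov_beta=np.zeros((2, 2)),
            term_names=[], fixed_names=["intercept", "sex_male"],
            covariances={}, blups={}, theta=np.zeros(0), loglik=0.0,
            n_obs=0, n_fixed=2, n_theta=0, converged=True)
        fit = AttendanceFit(glmm=glmm, spec=ModelSpec.adult(),
                            summary=pd.DataFrame(), variance_components={},
                            age_center=None, age_scale=None,
                            units=pd.DataFrame())
        pred = predict_attendance(fit, pd.DataFrame(dict(sex=["f", "m"])),
                                  marginal=False, n_draws=200, seed=0)
        assert pred.probability.iloc[0] == pytest.approx(expit(-0.4), abs=1e-9)
        assert pred.probability.iloc[1] == pytest.approx(expit(0.6), abs=1e-9)

    def test_quadratic_symmetry_when_linear_term_zero(self):
        beta = np.array([0.2, 0.0, -0.5])
        glmm = GLMMFit(
            beta=beta, se_beta=np.zeros(3), vcov_beta=np.zeros((3, 3)),
            term_names=[], fixed_names=["intercept", "age", "age2"],
            covariances={}, blups={}, theta=np.zeros(0), loglik=0.0,
            n_obs=0, n_fixed=3, n_theta=0, converged=True)
        fit = AttendanceFit(glmm=glmm, spec=ModelSpec.juvenile(),
                            summary=pd.DataFrame(), variance_components={},
                            age_center=3.0, age_scale=1.5,
                            units=pd.DataFrame())
        pred = predict_attendance(fit, pd.DataFrame(dict(age=[2.0, 4.0])),
                                  marginal=False, n_draws=100, seed=0)
        assert pred.probability.iloc[0] == pytest.approx(
            pred.probability.iloc[1], abs=1e-12)


class TestClassificationAccuracy:
    @staticmethod
    def _fake_fit(y, p, w=None):
        n = len(y)
        glmm = GLMMFit(
            beta=np.zeros(1), se_beta=np.zeros(1), vcov_beta=np.zeros((1, 1)),
            term_names=[], fixed_names=["intercept"], covariances={},
            blups={}, theta=np.zeros(0), loglik=0.0, n_obs=n, n_fixed=1,
            n_theta=0, converged=True, fitted=np.asarray(p, float),
            _y=np.asarray(y, float),
            _weights=np.ones(n) if w is None else np.asarray(w, float))
        return AttendanceFit(glmm=glmm, spec=ModelSpec.adult(),
                             summary=pd.DataFrame(), variance_components={},
                             age_center=None, age_scale=None,
                             units=pd.DataFrame())

    def test_perfect_separation_scores_one(self):
        y = np.array([0, 0, 1, 1, 1.0])
        p = np.array([0.1, 0.2, 0.9, 0.8, 0.95])
        assert classification_accuracy(self._fake_fit(y, p)) == 1.0

    def test_constant_probability_above_threshold(self):
        # 60% ones, constant fitted 0.7 > threshold 0.6 -> all classified 1
        y = np.array([1] * 6 + [0] * 4, dtype=float)
        p = np.full(10, 0.7)
        assert classification_accuracy(self._fake_fit(y, p)) == pytest.approx(0.6)


class TestBinnedResiduals:
    def test_single_bin_mean_residual_near_zero(self, juvenile_fit):
        fit, _ = juvenile_fit
        table = binned_residuals(fit, n_bins=1)
        assert abs(table.mean_residual.iloc[0]) < 0.02

    def test_too_many_bins_rejected(self, juvenile_fit):
        fit, _ = juvenile_fit
        with pytest.raises(ValueError):
            binned_residuals(fit, n_bins=10**7)

    def test_omitted_quadratic_shows_systematic_pattern(self):
        # quadratic truth fitted with a linear-only model: extreme fitted
        # bins overpredict (negative residuals), the centre underpredicts
        rng = np.random.default_rng(2)
        n = 4000
        x = rng.uniform(-2, 2, n)
        eta = 0.5 - 1.2 * x**2
        y = (rng.random(n) < expit(eta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        g = fit_glmm(y, X, [], fixed_names=["int", "x"])
        fit = AttendanceFit(glmm=g, spec=ModelSpec.adult(),
                            summary=pd.DataFrame(), variance_components={},
                            age_center=None, age_scale=None,
                            units=pd.DataFrame())
        table = binned_residuals(fit, n_bins=10)
        assert (~table.within).sum() >= 3

    def test_well_specified_fit_mostly_within_bands(self, juvenile_fit):
        fit, _ = juvenile_fit
        table = binned_residuals(fit, n_bins=15)
        assert table.within.mean() >= 0.8

    def test_plot_artifact_written(self, juvenile_fit, tmp_path):
        fit, _ = juvenile_fit
        path = tmp_path / "br.png"
        binned_residuals(fit, n_bins=10, plot_path=path)
        assert path.stat().st_size > 0


class TestRepeatability:
    def test_closed_form(self):
        assert latent_repeatability(1.0, 0.0) == pytest.approx(
            1 / (1 + np.pi**2 / 3), abs=1e-12)
        assert latent_repeatability(0.0, 2.0) == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r = latent_repeatability(rng.uniform(0, 10), rng.uniform(0, 10))
            assert 0 <= r <= 1

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            latent_repeatability(-1.0)

    def test_bootstrap_interval_brackets_point(self, juvenile_fit):
        _, units = juvenile_fit
        spec = ModelSpec.juvenile(age_center=3.0, age_scale=1.5)
        spec.random_bird_winter = False
        fit = fit_attendance_model(units, spec)
        rep = adjusted_repeatability(fit, n_boot=8, seed=3)
        assert 0 <= rep["lower"] <= rep["upper"] <= 1

    def test_requires_bird_and_winter_terms(self, juvenile_fit):
        fit, _ = juvenile_fit
        broken = AttendanceFit(glmm=fit.glmm, spec=fit.spec,
                               summary=fit.summary, variance_components={},
                               age_center=3.0, age_scale=1.5,
                               units=fit.units)
        broken.glmm = fit.glmm
        # the full fit has both terms, so this should work
        assert 0 <= adjusted_repeatability(fit)["R"] <= 1


class TestCramersV:
    def test_identical_binary_vectors(self):
        a = [0, 1, 1, 0, 1, 0]
        v, p = cramers_v(a, a)
        assert v == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # table [[30,10],[10,30]]: chi2 = 20, n = 80 -> V = 0.5
        a = [0] * 40 + [1] * 40
        b = [0] * 30 + [1] * 10 + [0] * 10 + [1] * 30
        v, p = cramers_v(a, b)
        assert v == pytest.approx(0.5, abs=1e-12)
        assert p < 0.01

    def test_independent_large_sample_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 100_000)
        b = rng.integers(0, 2, 100_000)
        v, _ = cramers_v(a, b)
        assert v < 0.02

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            cramers_v([0, 0, 0], [0, 1, 0])


class TestPlasticityMortalitySuite:
    def test_orthogonal_design_unit_vifs(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(64),
                             np.repeat([-1, 1], 32),
                             np.tile(np.repeat([-1, 1], 16), 2)])
        vif = variance_inflation_factors(X, ["intercept", "a", "b"])
        assert np.allclose(vif.vif, 1.0, atol=1e-9)

    @pytest.mark.parametrize("kind,expected", [
        ("plasticity", "plasticity"), ("selective", "selective_mortality")])
    def test_scenarios_labelled(self, kind, expected, recwarn):
        units, deaths = simulate_mortality_scenario(kind, seed=5)
        res = plasticity_mortality_suite(units, deaths)
        assert res.interpretation == expected
        assert set(res.fits) == {"age", "age_bird", "longevity_bird",
                                 "age_longevity_bird"}

    def test_longevity_below_observed_age_rejected(self):
        units, deaths = simulate_mortality_scenario("plasticity", n_birds=5,
                                                    seed=1)
        deaths["longevity"] = 1
        with pytest.raises(ValueError):
            plasticity_mortality_suite(units, deaths)

    def test_single_longevity_level_skips_models(self, recwarn):
        units, deaths = simulate_mortality_scenario("plasticity", n_birds=8,
                                                    seed=2)
        deaths["longevity"] = units.groupby("bird_id").age.max().reindex(
            deaths.bird_id).to_numpy()
        deaths["longevity"] = deaths.longevity.max()
        units = units[units.age <= deaths.longevity.iloc[0]]
        d2 = deaths.copy()
        # force one longevity level
        res = plasticity_mortality_suite(units, d2)
        assert "longevity_bird" not in res.fits or d2.longevity.nunique() > 1


class TestCompareModels:
    def _units(self, seed=3):
        cfg = PopulationConfig(n_juvenile_tagged=100, n_adult_tagged=0,
                               n_winters=5, seed=seed)
        pop, _, tt = make_fixture(cfg, TRUTH)
        return truth_interval_units(tt, pop)

    def test_identical_models_zero_difference(self):
        units = self._units()
        spec = ModelSpec.juvenile(age_center=3.0, age_scale=1.5)
        f1 = fit_attendance_model(units, spec)
        f2 = fit_attendance_model(units, spec)
        table = compare_models({"a": f1.glmm, "b": f2.glmm})
        assert abs(table.elpd_diff.iloc[1]) < 0.5

    def test_quadratic_truth_prefers_quadratic(self):
        units = self._units(seed=4)
        full = fit_attendance_model(
            units, ModelSpec.juvenile(age_center=3.0, age_scale=1.5))
        linear = fit_attendance_model(
            units, ModelSpec(cohort="juvenile",
                             fixed=("age", "sex", "breeding_status"),
                             age_center=3.0, age_scale=1.5))
        table = compare_models({"quadratic": full.glmm,
                                "linear": linear.glmm})
        assert table.model.iloc[0] == "quadratic"

    def test_mismatched_data_rejected(self):
        units = self._units()
        f1 = fit_attendance_model(
            units, ModelSpec.juvenile(age_center=3.0, age_scale=1.5))
        units2 = units.copy()
        units2["attendance"] = 1 - units2.attendance
        f2 = fit_attendance_model(
            units2, ModelSpec.juvenile(age_center=3.0, age_scale=1.5))
        with pytest.raises(ValueError):
            compare_models({"a": f1.glmm, "b": f2.glmm})
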