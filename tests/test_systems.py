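"""Simultaneous-system fitting: additivity, NSUR oracle equivalence,
decomposition share algebra, climate parameterization and screening."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from oakbiomass import (CARModel, FitError, GeneratorConfig, WeightSpec,
                        fit_aggregation, fit_car, fit_climate_aggregation,
                        fit_decomposition, generate_trees,
                        select_climate_factors, zero_noise_config)
from oakbiomass.data import CLIMATE_KEYS, size_arrays
from oakbiomass.reference import (AGGREGATION_BIOMASS, CLIMATE_AGGREGATION_BIOMASS,
                                  CLIMATE_ASSIGNMENT)
from oakbiomass.synthetic import climate_screening_population
from oakbiomass.systems import ClimateCARModel, CompatibleSystemFit


def _agg_truth():
    return {c: CARModel(*AGGREGATION_BIOMASS[c], response=c)
            for c in ("stem", "branch", "leaf")}


def _climate_truth():
    return {c: ClimateCARModel(*CLIMATE_AGGREGATION_BIOMASS[c],
                               climate_variable=CLIMATE_ASSIGNMENT[c],
                               response=c)
            for c in ("stem", "branch", "leaf")}


class TestAggregation:
    def test_total_is_component_sum_by_construction(self, default_population):
        fit = fit_aggregation(default_population)
        d, h = size_arrays(default_population)
        comps = fit.predict_components(d, h)
        total = fit.predict_total(d, h)
        np.testing.assert_allclose(
            total, comps["stem"] + comps["branch"] + comps["leaf"],
            rtol=1e-12)

    def test_zero_noise_recovers_published_system(self):
        cfg = replace(zero_noise_config(seed=11), true_models=_agg_truth())
        recs = generate_trees(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # zero-noise covariance is singular
            fit = fit_aggregation(recs)
        for c, truth in AGGREGATION_BIOMASS.items():
            m = fit.models[c]
            est = (m.a0, m.a1) + ((m.a2,) if m.a2 is not None else ())
            np.testing.assert_allclose(est, truth, rtol=1e-4)

    def test_diagonal_sigma_equals_independent_fits(self, default_population):
        """With a forced diagonal equal-variance covariance the joint fit
        separates into the per-equation weighted fits (oracle equivalence)."""
        fit = fit_aggregation(default_population, sigma=np.eye(3))
        forms = {"stem": "bivariate", "branch": "univariate",
                 "leaf": "univariate"}
        for c, form in forms.items():
            solo = fit_car(default_population, c, form=form)
            m = fit.models[c]
            assert m.a0 == pytest.approx(solo.a0, rel=1e-6)
            assert m.a1 == pytest.approx(solo.a1, rel=1e-6)
            if m.a2 is not None:
                assert m.a2 == pytest.approx(solo.a2, rel=1e-6)

    def test_correlated_errors_show_up_in_sigma(self):
        """Two perfectly correlated component errors give an off-diagonal
        correlation near 1 in the estimated covariance."""
        rng = np.random.default_rng(21)
        from oakbiomass.data import TreeRecord
        d = rng.uniform(2, 30, 300)
        h = 1.3 + 24 * (1 - np.exp(-0.03 * d))
        shock = rng.standard_normal(300) * 0.3
        mult = np.exp(shock - 0.045)
        recs = [TreeRecord(tree_id=str(i), dbh=float(d[i]), height=float(h[i]),
                           age=40.0,
                           stem=float(0.1057 * d[i] ** 2.3113 * mult[i]),
                           branch=float(0.0069 * d[i] ** 2.9374 * mult[i]),
                           leaf=float(0.0162 * d[i] ** 2.0129))
                for i in range(300)]
        fit = fit_aggregation(recs, component_forms={"stem": "univariate",
                                                     "branch": "univariate",
                                                     "leaf": "univariate"})
        s = fit.sigma
        corr = s[0, 1] / np.sqrt(s[0, 0] * s[1, 1])
        assert corr == pytest.approx(1.0, abs=0.05)


class TestDecomposition:
    def test_share_algebra_degenerate_cases(self, default_population):
        fit = fit_decomposition(default_population)
        zero_g = replace(fit, proportion_models={
            "branch": CARModel(1e-300, 0.0), "leaf": CARModel(1e-300, 0.0)})
        sh = zero_g.shares(np.array([10.0]))
        assert sh["stem"][0] == pytest.approx(1.0)
        assert sh["branch"][0] == pytest.approx(0.0)
        unit_g = replace(fit, proportion_models={
            "branch": CARModel(1.0, 0.0), "leaf": CARModel(1.0, 0.0)})
        sh = unit_g.shares(np.array([10.0]))
        for v in sh.values():
            assert v[0] == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_shares_sum_to_one_everywhere(self, default_population):
        fit = fit_decomposition(default_population)
        rng = np.random.default_rng(5)
        d = rng.uniform(1.5, 31.5, 10_000)
        sh = fit.shares(d)
        np.testing.assert_allclose(sh["stem"] + sh["branch"] + sh["leaf"],
                                   1.0, atol=1e-12)
        for v in sh.values():
            assert np.all((v > 0) & (v < 1))

    def test_component_predictions_split_the_frozen_total(self,
                                                          default_population):
        total = fit_car(default_population, "aboveground", form="bivariate")
        fit = fit_decomposition(default_population, total_spec=total)
        assert fit.total_model is total          # frozen, not re-estimated
        d, h = size_arrays(default_population)
        comps = fit.predict_components(d, h)
        np.testing.assert_allclose(
            comps["stem"] + comps["branch"] + comps["leaf"],
            total.predict(d, h), rtol=1e-10)


class TestClimateAggregation:
    def test_zero_noise_recovers_effective_parameters(self):
        cfg = replace(zero_noise_config(seed=3), true_models=_climate_truth())
        recs = generate_trees(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_climate_aggregation(recs)
        truth = _climate_truth()
        for c in ("stem", "branch", "leaf"):
            key = truth[c].climate_variable
            cvals = np.percentile([r.climate[key] for r in recs], [10, 50, 90])
            for v in cvals:      # >= 3 distinct climate levels
                est = np.asarray(fit.models[c].effective(v))
                tr = np.asarray(truth[c].effective(v))
                np.testing.assert_allclose(est, tr, rtol=1e-4)

    def test_climate_prediction_reduces_to_car_at_cancelling_value(self):
        m = ClimateCARModel(c0=0.04, c01=0.002, e1=2.0, e11=-0.01,
                            climate_variable="TD")
        c = 5.0
        coeff, ed = m.effective(c)
        plain = CARModel(coeff, ed)
        d = np.linspace(2, 30, 50)
        np.testing.assert_allclose(m.predict(d, climate_value=c),
                                   plain.predict(d), rtol=1e-12)

    def test_additivity_holds_for_climate_system(self, default_population):
        fit = fit_climate_aggregation(default_population)
        d, h = size_arrays(default_population)
        clim = {key: np.array([r.climate[key] for r in default_population])
                for key in CLIMATE_KEYS}
        comps = fit.predict_components(d, h, clim)
        np.testing.assert_allclose(
            fit.predict_total(d, h, clim),
            comps["stem"] + comps["branch"] + comps["leaf"], rtol=1e-12)

    def test_rejects_unknown_indicator(self, default_population):
        with pytest.raises(ValueError):
            fit_climate_aggregation(default_population,
                                    climate_assignment={"stem": "DD_gt0"})


class TestClimateScreening:
    def test_planted_dependence_is_selected(self):
        recs = climate_screening_population(seed=1)
        assignment, report = select_climate_factors(recs)
        assert assignment["branch"] == "PAS"
        assert assignment["leaf"] == "TD"
        assert set(report["branch"]) == set(CLIMATE_KEYS)

    def test_component_equal_to_climate_column_gives_r_one(self):
        recs = climate_screening_population(seed=2)
        from dataclasses import replace as drep
        recs = [drep(r, branch=r.climate["PAS"]) for r in recs]
        _, report = select_climate_factors(recs)
        assert report["branch"]["PAS"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_climate_yields_empty_selection(self):
        recs = climate_screening_population(seed=3)
        from dataclasses import replace as drep
        flat = {k: 1.0 for k in CLIMATE_KEYS}
        flat["RH"] = 50.0
        recs = [drep(r, climate=flat) for r in recs]
        with pytest.warns(UserWarning):
            assignment, report = select_climate_factors(recs)
        assert assignment == {}
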