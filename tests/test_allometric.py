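"""Weighted CAR power-law fitting: prediction arithmetic, weights, recovery,
and the consequences of heteroscedasticity weighting."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oakbiomass import (CARModel, FitError, GeneratorConfig, WeightSpec,
                        compute_weights, fit_car, fit_car_xy, generate_trees,
                        predict_car, zero_noise_config)
from oakbiomass.reference import INDEPENDENT_BIOMASS


class TestPredict:
    def test_published_aboveground_model_at_10cm(self):
        m = CARModel(0.0956, 2.4803)
        assert m.predict(10.0) == pytest.approx(28.89, abs=0.01)

    def test_exponent_zero_is_identity(self):
        assert predict_car(CARModel(1.0, 0.0), 123.4) == 1.0

    def test_unit_base_collapses_to_coefficient(self):
        m = CARModel(0.0588, 2.1205, 0.6270)
        assert m.predict(1.0, 1.0) == pytest.approx(0.0588, rel=1e-12)

    def test_argument_errors(self):
        biv = CARModel(0.05, 2.0, 0.6)
        with pytest.raises(ValueError):
            biv.predict(10.0)                 # missing height
        with pytest.raises(ValueError):
            CARModel(0.1, 2.0).predict(-1.0)  # non-positive dbh
        with pytest.raises(ValueError):
            CARModel(0.1, 2.0).predict(10.0, 5.0)  # height for univariate

    def test_agrees_with_log_domain_evaluation(self, rng):
        d = rng.uniform(1.5, 31.0, 200)
        h = rng.uniform(2.0, 20.0, 200)
        m = CARModel(0.0445, 1.7307, 1.0389)
        direct = m.predict(d, h)
        logged = np.exp(np.log(m.a0) + m.a1 * np.log(d) + m.a2 * np.log(h))
        assert np.allclose(direct, logged, rtol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(d=st.floats(0.1, 100), scale=st.floats(0.01, 100))
    def test_prediction_scales_with_coefficient(self, d, scale):
        base = CARModel(0.1, 2.3)
        assert base.scaled(scale).predict(d) == pytest.approx(
            scale * base.predict(d), rel=1e-12)


class TestWeights:
    def test_inverse_mean_examples(self):
        spec = WeightSpec(power=1.0)
        assert np.allclose(compute_weights([1.0, 4.0], spec), [1.0, 0.25])
        assert np.allclose(compute_weights([100.0], WeightSpec(power=2.0)),
                           [1e-4])

    def test_power_zero_gives_unit_weights(self):
        assert np.allclose(compute_weights([3.0, 7.0], WeightSpec(power=0.0)),
                           [1.0, 1.0])

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            compute_weights([1.0, 0.0], WeightSpec())


class TestFit:
    def test_zero_noise_recovery(self, noiseless_population):
        for comp in ("stem", "branch", "leaf"):
            true = INDEPENDENT_BIOMASS[(comp, "univariate")]
            m = fit_car(noiseless_population, comp)
            assert m.a0 == pytest.approx(true[0], rel=1e-6)
            assert m.a1 == pytest.approx(true[1], rel=1e-6)
            assert m.diagnostics.converged

    def test_degenerate_response_raises(self, rng):
        d = rng.uniform(2, 30, 20)
        with pytest.raises(FitError):
            fit_car_xy(d, None, np.full(20, 5.0))

    def test_weight_modes_agree_on_homoscedastic_data(self, rng):
        d = rng.uniform(5, 30, 400)
        y = 0.1 * d ** 2.3 + rng.normal(0, 0.5, 400)
        mw = fit_car_xy(d, None, y, weights=WeightSpec())
        mu = fit_car_xy(d, None, y, weights=WeightSpec(mode="none"))
        assert mw.a1 == pytest.approx(mu.a1, rel=0.02)

    def test_response_scaling_scales_coefficient_only(self, default_population):
        m = fit_car(default_population, "stem")
        scaled = fit_car(default_population, lambda r: 0.4820 * r.stem)
        assert scaled.a0 == pytest.approx(0.4820 * m.a0, rel=1e-6)
        assert scaled.a1 == pytest.approx(m.a1, rel=1e-8)

    def test_median_exponent_recovery_within_2pct(self):
        """Monte-Carlo oracle: CV=0.3 multiplicative noise, n=175."""
        true_a1 = INDEPENDENT_BIOMASS[("stem", "univariate")][1]
        errs = []
        for rep in range(200):
            cfg = replace(GeneratorConfig(seed=50_000 + rep, root_subsample=0),
                          noise_cv_per_component={"stem": 0.3, "branch": 0.3,
                                                  "leaf": 0.3, "root": 0.3})
            m = fit_car(generate_trees(cfg), "stem")
            errs.append(abs(m.a1 - true_a1) / true_a1)
        assert np.median(errs) < 0.02

    def test_weighting_beats_ols_under_heteroscedasticity(self):
        """Var proportional to mean^2: the weighted fit has lower exponent
        RMSE than the unweighted fit over 200 study-size replicates."""
        rng = np.random.default_rng(777)
        true = CARModel(0.1057, 2.3113)
        err_w, err_u = [], []
        for _ in range(200):
            d = rng.uniform(1.5, 31.5, 175)
            mu = true.predict(d)
            sigma = np.sqrt(np.log1p(0.5 ** 2))
            y = mu * np.exp(rng.standard_normal(175) * sigma - sigma ** 2 / 2)
            err_w.append(fit_car_xy(d, None, y).a1 - true.a1)
            err_u.append(fit_car_xy(d, None, y,
                                    weights=WeightSpec(mode="none")).a1 - true.a1)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
        assert rmse(err_w) < rmse(err_u)
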