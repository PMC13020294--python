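"""Root-shoot ratio model: joint SUR recovery, prediction identities, and
the subsample error-propagation adjustment."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oakbiomass import (GeneratorConfig, RootShootModel, adjust_mpe,
                        fit_root_shoot, generate_trees, mpe_adjustment,
                        predict_root, zero_noise_config)
from oakbiomass.allometric import CARModel
from oakbiomass.reference import ROOT_SHOOT_BIOMASS


class TestAdjustMpe:
    def test_k_one_or_r_zero_leave_mpe_unchanged(self):
        assert adjust_mpe(1.0, 0.9, 16.02) == pytest.approx(16.02)
        assert adjust_mpe(175 / 53, 0.0, 16.02) == pytest.approx(16.02)

    def test_hand_computed_adjustment(self):
        got = adjust_mpe(175 / 53, 0.9, 16.02)
        assert got == pytest.approx(
            math.sqrt(1 - (1 - 53 / 175) * 0.81) * 16.02, rel=1e-12)
        assert got == pytest.approx(10.57, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            adjust_mpe(0.5, 0.5, 10.0)
        with pytest.raises(ValueError):
            adjust_mpe(2.0, 1.5, 10.0)

    @settings(derandomize=True, max_examples=200)
    @given(K=st.floats(1.0, 50.0), r=st.floats(-1.0, 1.0),
           mpe=st.floats(0.0, 100.0))
    def test_never_exceeds_input_and_monotone(self, K, r, mpe):
        out = adjust_mpe(K, r, mpe)
        assert out <= mpe + 1e-12
        # monotone decreasing in |r| and in K
        assert out >= adjust_mpe(K, min(1.0, abs(r) + 0.1), mpe) - 1e-12
        assert out >= adjust_mpe(K + 1.0, r, mpe) - 1e-12


class TestPredictRoot:
    def test_unit_ratio_returns_aboveground(self):
        m = RootShootModel(b0=1.0, b1=0.0)
        assert predict_root(m, 12.0, aboveground_prediction=77.7) == 77.7

    def test_hand_computed_ratio_prediction(self):
        m = RootShootModel(b0=0.6926, b1=-0.2848)
        got = predict_root(m, 10.0, aboveground_prediction=28.9)
        assert got == pytest.approx(0.6926 * 10 ** -0.2848 * 28.9, rel=1e-12)
        assert got == pytest.approx(10.39, abs=0.01)

    def test_zero_aboveground_gives_zero_root(self):
        m = RootShootModel(b0=0.7, b1=-0.3)
        assert predict_root(m, 15.0, aboveground_prediction=0.0) == 0.0

    def test_ratio_identity_against_any_aboveground_source(self):
        m = RootShootModel(b0=0.6926, b1=-0.2848,
                           aboveground=CARModel(0.0956, 2.4803))
        d = np.linspace(2, 30, 20)
        agb = m.aboveground.predict(d)
        np.testing.assert_allclose(predict_root(m, d, aboveground_prediction=agb)
                                   / agb, m.ratio(d), rtol=1e-12)


class TestFitRootShoot:
    def test_zero_noise_recovers_published_ratio(self):
        """Ratio truth applied on top of a known power-law aboveground
        model is recovered exactly by the joint SUR fit."""
        from oakbiomass.data import TreeRecord
        rng = np.random.default_rng(13)
        d = rng.uniform(2, 30, 53)
        agb = 0.0956 * d ** 2.4803
        b0, b1 = ROOT_SHOOT_BIOMASS["univariate"]
        root = b0 * d ** b1 * agb
        recs = [TreeRecord(tree_id=str(i), dbh=float(d[i]), height=10.0,
                           age=40.0, stem=float(0.65 * agb[i]),
                           branch=float(0.30 * agb[i]),
                           leaf=float(0.05 * agb[i]), root=float(root[i]))
                for i in range(53)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_root_shoot(recs)
        assert m.b0 == pytest.approx(b0, rel=1e-4)
        assert m.b1 == pytest.approx(b1, rel=1e-4)
        assert m.aboveground.a0 == pytest.approx(0.0956, rel=1e-4)
        assert m.aboveground.a1 == pytest.approx(2.4803, rel=1e-4)

    def test_constant_ratio_data_recovers_flat_exponent(self):
        from oakbiomass.data import TreeRecord
        rng = np.random.default_rng(3)
        d = rng.uniform(2, 30, 60)
        agb = 0.0956 * d ** 2.4803
        recs = [TreeRecord(tree_id=str(i), dbh=float(d[i]), height=10.0,
                           age=40.0, stem=float(0.6 * agb[i]),
                           branch=float(0.3 * agb[i]),
                           leaf=float(0.1 * agb[i]), root=float(0.45 * agb[i]))
                for i in range(60)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_root_shoot(recs)
        assert m.b1 == pytest.approx(0.0, abs=1e-6)
        assert m.b0 == pytest.approx(0.45, rel=1e-6)

    def test_requires_enough_root_records(self):
        recs = generate_trees(replace(GeneratorConfig(seed=2),
                                      root_subsample=3))
        with pytest.raises(ValueError):
            fit_root_shoot(recs)


def test_data_driven_adjustment_uses_sample_ratio(default_population):
    adj = mpe_adjustment(default_population, mpe_small=16.02)
    assert adj.K == pytest.approx(175 / 53)
    assert abs(adj.r) <= 1
    assert adj.mpe_adjusted <= adj.mpe_small
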