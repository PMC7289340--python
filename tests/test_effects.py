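"""Contrast inference: oracle equivalence, Wald algebra, compensation."""

import numpy as np
import pandas as pd
import pytest

from bmigrowth.design import ModelSpec, population_row
from bmigrowth.effects import (
    ebf_effect,
    glh_test,
    grs_compensation,
    marginal_grs_effect,
)

from conftest import random_interaction_model


def _predict(model, age, grs, ebf):
    row = population_row(model.spec, age, grs, ebf)
    return float(row @ model.coef.to_numpy())


class TestMarginalGrsEffect:
    def test_null_grs_coefficients_give_zero_effect_p_one(self):
        m = random_interaction_model(0)
        for c in m.coef.index:
            if "grs" in c:
                m.coef[c] = 0.0
        e = marginal_grs_effect(m, 7.0)
        assert e.estimate == 0.0
        # a zero contrast on non-zero covariance still has se > 0; p from z=0
        assert e.p_value == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_prediction_difference(self, seed):
        m = random_interaction_model(seed)
        rng = np.random.default_rng(seed + 1000)
        age = rng.uniform(0.1, 19.9)
        g0 = rng.uniform(0, 7)
        ebf = rng.uniform(0, 6)
        e = marginal_grs_effect(m, age, delta_grs=2.5, ebf_fixed=ebf)
        brute = _predict(m, age, g0 + 2.5, ebf) - _predict(m, age, g0, ebf)
        assert abs(e.estimate - brute) < 1e-10

    def test_independent_of_baseline_grs(self):
        m = random_interaction_model(5)
        a = _predict(m, 10.0, 2.5, 1.0) - _predict(m, 10.0, 0.0, 1.0)
        b = _predict(m, 10.0, 9.0, 1.0) - _predict(m, 10.0, 6.5, 1.0)
        assert abs(a - b) < 1e-10

    def test_age_outside_domain_rejected(self):
        m = random_interaction_model(2)
        with pytest.raises(ValueError, match="domain"):
            marginal_grs_effect(m, 25.0)


class TestEbfEffect:
    def test_zero_months_gives_exactly_zero(self):
        m = random_interaction_model(3)
        e = ebf_effect(m, 18.0, 0.0, 5.0)
        assert e.estimate == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_prediction_difference(self, seed):
        m = random_interaction_model(seed + 50)
        rng = np.random.default_rng(seed + 2000)
        age, months, g = rng.uniform(0.1, 19.9), rng.uniform(0, 6), rng.uniform(0, 10)
        e = ebf_effect(m, age, months, g)
        brute = _predict(m, age, g, 0.0) - _predict(m, age, g, months)
        assert abs(e.estimate - brute) < 1e-10

    def test_exposure_missing_from_model_rejected(self):
        m = random_interaction_model(7, spec=ModelSpec(exposure=None, interactions=("grs",)))
        with pytest.raises(ValueError, match="without a breastfeeding exposure"):
            ebf_effect(m, 18.0, 5.0, 5.0)

    def test_ci_is_plus_minus_1p96_se_and_ordered(self):
        m = random_interaction_model(8)
        e = ebf_effect(m, 15.0, 5.0, 7.5)
        assert e.ci_low <= e.ci_high
        assert abs((e.ci_high - e.estimate) - 1.96 * e.se) < 1e-12
        assert abs((e.estimate - e.ci_low) - 1.96 * e.se) < 1e-12


class TestGlh:
    def test_zero_contrast_gives_zero_estimate_p_one(self):
        m = random_interaction_model(9)
        est, se, z, p = glh_test(m, np.zeros(len(m.coef)))
        assert est == 0.0 and p == 1.0

    def test_single_row_squared_equals_chi2_statistic(self):
        m = random_interaction_model(10)
        L = population_row(m.spec, 12.0, 5.0, 3.0)
        est, se, z, p1 = glh_test(m, L)
        ests, chi2, df, p2 = glh_test(m, L[None, :])
        assert df == 1
        assert abs(z**2 - chi2) < 1e-8
        assert abs(p1 - p2) < 1e-10

    def test_singular_stacked_contrast_uses_rank(self):
        m = random_interaction_model(11)
        L = population_row(m.spec, 12.0, 5.0, 3.0)
        stacked = np.vstack([L, L])  # rank 1
        with pytest.warns(UserWarning, match="singular"):
            _, chi2, df, p = glh_test(m, stacked)
        assert df == 1

    def test_wrong_length_contrast_rejected(self):
        m = random_interaction_model(12)
        with pytest.raises(ValueError, match="contrast length"):
            glh_test(m, np.zeros(3))

    def test_p_monotone_in_effect_size(self):
        m = random_interaction_model(13)
        L = population_row(m.spec, 10.0, 5.0, 5.0)
        ps = []
        for scale in (0.5, 1.0, 2.0):
            mm = random_interaction_model(13)
            mm.coef[:] = m.coef.to_numpy() * scale
            ps.append(glh_test(mm, L)[3])
        assert ps[0] > ps[1] > ps[2]


class TestCompensation:
    def test_zero_reduction_gives_zero_deciles(self):
        m = random_interaction_model(14)
        for c in m.coef.index:
            if "ebf" in c:
                m.coef[c] = 0.0
        # ensure a positive GRS slope so compensation is defined
        m.coef["agek3:grs"] = abs(m.coef["agek3:grs"]) + 0.1
        comp = grs_compensation(m, 18.0, 7.5, 5.0)
        assert comp.bmi_reduction == 0.0 and comp.delta_deciles == 0.0

    def test_closed_form_half_unit_example(self):
        """Slope 0.5 kg/m^2 per unit with a 1.0 kg/m^2 reduction must
        compensate exactly 2 score units."""
        spec = ModelSpec(exposure="ebf", confounders=())
        m = random_interaction_model(15, spec=spec)
        m.coef[:] = 0.0
        m.coef["grs"] = 0.5  # age-constant slope
        m.coef["ebf"] = -0.2  # 1.0 reduction for 5 months
        comp = grs_compensation(m, 18.0, 5.0, 5.0)
        assert abs(comp.bmi_reduction - 1.0) < 1e-12
        assert abs(comp.delta_deciles - 2.0) < 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_identity_deciles_times_slope_equals_reduction(self, seed):
        m = random_interaction_model(seed + 100)
        try:
            comp = grs_compensation(m, 15.0, 5.0, 4.0)
        except ValueError:
            return  # random slope happened to be negative: correctly refused
        assert abs(comp.delta_deciles * comp.grs_slope_ref - comp.bmi_reduction) < 1e-10

    def test_negative_slope_rejected(self):
        m = random_interaction_model(16)
        for c in m.coef.index:
            if "grs" in c:
                m.coef[c] = -abs(m.coef[c]) - 0.01
        with pytest.raises(ValueError, match="compensation undefined"):
            grs_compensation(m, 18.0, 5.0, 5.0)


def test_contrasts_invariant_to_confounder_presence(small_study):
    """Fitting with and without confounders changes estimates, but within
    one model the contrast rows put exactly zero weight on confounders."""
    from bmigrowth.design import DEFAULT_CONFOUNDERS

    spec = ModelSpec(confounders=DEFAULT_CONFOUNDERS)
    m = random_interaction_model(17, spec=spec)
    e = ebf_effect(m, 12.0, 5.0, 5.0)
    n_conf = len(spec.fixed_columns()) - 28
    assert np.all(e.L[-n_conf:] == 0.0)
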