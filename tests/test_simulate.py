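"""Synthetic cohort generator: distributions, noise model, missingness."""

import numpy as np
import pandas as pd
import pytest

from bmigrowth import (
    apply_missingness,
    default_truth,
    generate_bmi,
    generate_cohort,
    simulate_study,
)
from bmigrowth.adiposity import curve_stationary
from bmigrowth.simulate import ConfigurationError


def _grs_for(cohort, value=5.0):
    return pd.Series(value, index=cohort["child_id"].to_numpy(), name="scaled_score")


class TestGenerateCohort:
    def test_empty_cohort_has_headers_only(self):
        truth = default_truth(n_children=0)
        cohort, dosages = generate_cohort(truth)
        assert len(cohort) == 0 and len(dosages) == 0
        assert "ebf_months" in cohort.columns and "child_id" in dosages.columns

    def test_zero_frequency_snp_dosage_identically_zero(self):
        truth = default_truth(n_children=50, seed=1)
        truth.allele_freqs = truth.allele_freqs.copy()
        truth.allele_freqs[3] = 0.0
        _, dosages = generate_cohort(truth)
        assert (dosages.iloc[:, 4] == 0.0).all()  # column 0 is child_id

    def test_dosage_mean_matches_binomial_moment(self):
        """Mean dosage at frequency p is 2p within 3 standard errors."""
        n, p = 5000, 0.3
        truth = default_truth(n_children=n, seed=7, allele_freqs=np.full(5, p))
        _, dosages = generate_cohort(truth)
        se = np.sqrt(2 * p * (1 - p) / n)
        assert abs(dosages["snp0"].mean() - 2 * p) < 3 * se

    def test_breastfeeding_durations_ordered_and_bounded(self):
        truth = default_truth(n_children=400, seed=2)
        cohort, _ = generate_cohort(truth)
        assert (cohort["ebf_months"] >= 0).all()
        assert (cohort["ebf_months"] <= 6).all()
        assert (cohort["bf_months"] >= cohort["ebf_months"] - 1e-12).all()
        assert (cohort["bf_months"] <= 24).all()

    def test_centered_covariates_have_zero_mean(self):
        truth = default_truth(n_children=300, seed=3)
        cohort, _ = generate_cohort(truth)
        assert abs(cohort["gestational_age_c"].mean()) < 1e-8
        assert abs(cohort["maternal_bmi_c"].mean()) < 1e-8

    def test_seed_reproducibility_byte_identical(self):
        truth = default_truth(n_children=80, seed=11)
        a = generate_cohort(truth)
        b = generate_cohort(default_truth(n_children=80, seed=11))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_asymmetric_correlation_matrix_names_entry(self):
        bad = np.array([[1.0, 0.3, 0.1], [0.2, 1.0, 0.0], [0.1, 0.0, 1.0]])
        with pytest.raises(ConfigurationError, match=r"\(0, 1\)"):
            default_truth(n_children=10, random_effect_corr=bad)

    def test_non_positive_definite_correlation_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ConfigurationError, match="positive definite"):
            default_truth(n_children=10, random_effect_corr=bad)


class TestGenerateBmi:
    def test_noise_free_bmi_equals_population_curve(self):
        truth = default_truth(
            n_children=20, seed=5, residual_sd=0.0,
            random_effect_sd=(0.0, 0.0, 0.0), visit_jitter_sd=0.0,
        )
        cohort, _ = generate_cohort(truth)
        long = generate_bmi(truth, cohort, _grs_for(cohort))
        # closed-form curve from the truth coefficients
        from bmigrowth.design import build_design

        d = build_design(cohort, _grs_for(cohort).rename_axis("child_id").reset_index(),
                         long.assign(bmi=0.0), truth.model_spec)
        beta = np.array([truth.true_fixed_coefs.get(c, 0.0) for c in d.columns])
        np.testing.assert_allclose(long["bmi"].to_numpy(), d.X @ beta, atol=1e-10)

    def test_truth_curve_has_peak_and_rebound(self):
        """The default population curve peaks in infancy and rebounds in
        childhood -- located here by grid search, independently of the
        analytic root finder."""
        truth = default_truth()
        from bmigrowth.adiposity import _coef_vector
        from bmigrowth.design import ModelSpec
        from bmigrowth.splines import spline_basis

        spec = truth.model_spec
        from bmigrowth.design import population_row

        ts = np.linspace(0.01, 19.9, 8000)
        vec = _coef_vector(spec, truth.true_fixed_coefs)
        rows = np.stack([population_row(spec, t, grs=5.0, exposure_months=0.0) for t in ts[::40]])
        curve = rows @ vec
        tt = ts[::40]
        ap_region = (tt > 0.25) & (tt < 1.5)
        ar_region = (tt > 3.0) & (tt < 8.0)
        ap = tt[ap_region][np.argmax(curve[ap_region])]
        ar = tt[ar_region][np.argmin(curve[ar_region])]
        assert 0.25 < ap < 1.5
        assert 3.0 < ar < 8.0

    def test_doubling_residual_sd_doubles_residual_spread(self):
        base = default_truth(n_children=2000, seed=8, random_effect_sd=(0.0, 0.0, 0.0),
                             visit_jitter_sd=0.0)
        doubled = base.replace(residual_sd=2 * base.residual_sd, seed=8)
        sds = []
        for truth in (base, doubled):
            cohort, _ = generate_cohort(truth)
            long = generate_bmi(truth, cohort, _grs_for(cohort))
            noise_free = truth.replace(residual_sd=0.0)
            mu = generate_bmi(noise_free, cohort, _grs_for(cohort))
            sds.append(np.std(long["bmi"].to_numpy() - mu["bmi"].to_numpy()))
        ratio = sds[1] / sds[0]
        n = 2000 * 11
        mc = 3.0 / np.sqrt(2 * n)  # 3x the MC error of an sd ratio
        assert abs(ratio - 2.0) < 2.0 * mc + 0.02

    def test_marginal_variance_matches_analytic_form(self):
        """Var(BMI | age) = z' Sigma_b z + sigma^2 for the random-effect
        design row z at that age."""
        truth = default_truth(n_children=3000, seed=13, visit_jitter_sd=0.0)
        cohort, _ = generate_cohort(truth)
        long = generate_bmi(truth, cohort, _grs_for(cohort))
        age = truth.visit_schedule[5]  # 7 years
        at_age = long[np.isclose(long["age_years"], age)]
        z = np.array([1.0, age, age**2])
        expected = z @ truth.random_effect_cov() @ z + truth.residual_sd**2
        observed = at_age["bmi"].var()
        assert abs(observed / expected - 1.0) < 0.15

    def test_unknown_truth_coefficient_rejected(self):
        truth = default_truth(n_children=5, seed=1)
        truth.true_fixed_coefs = dict(truth.true_fixed_coefs, nonsense_column=1.0)
        cohort, _ = generate_cohort(truth)
        with pytest.raises(ConfigurationError, match="nonsense_column"):
            generate_bmi(truth, cohort, _grs_for(cohort))


class TestMissingness:
    def test_huge_intercept_retains_everything(self):
        truth = default_truth(n_children=60, seed=4,
                              missingness_coefs={"intercept": 50.0})
        cohort, _ = generate_cohort(truth)
        long = generate_bmi(truth, cohort, _grs_for(cohort))
        thinned, cohort2 = apply_missingness(truth, long, cohort)
        pd.testing.assert_frame_equal(thinned, long)
        pd.testing.assert_frame_equal(cohort2, cohort)

    def test_huge_negative_intercept_drops_everything_with_warning(self):
        truth = default_truth(n_children=40, seed=4,
                              missingness_coefs={"intercept": -50.0})
        cohort, _ = generate_cohort(truth)
        long = generate_bmi(truth, cohort, _grs_for(cohort))
        with pytest.warns(UserWarning, match="every BMI record"):
            thinned, cohort2 = apply_missingness(truth, long, cohort)
        assert len(thinned) == 0 and len(cohort2) == 0

    def test_zero_intercept_retains_about_half(self):
        truth = default_truth(n_children=1000, seed=6,
                              missingness_coefs={"intercept": 0.0})
        cohort, _ = generate_cohort(truth)
        long = generate_bmi(truth, cohort, _grs_for(cohort))
        thinned, _ = apply_missingness(truth, long, cohort)
        frac = len(thinned) / len(long)
        se = 0.5 / np.sqrt(len(long))
        assert abs(frac - 0.5) < 3 * se

    def test_children_without_records_dropped_from_both_tables(self):
        truth = default_truth(n_children=200, seed=9,
                              missingness_coefs={"intercept": -1.5})
        cohort, _ = generate_cohort(truth)
        long = generate_bmi(truth, cohort, _grs_for(cohort))
        thinned, cohort2 = apply_missingness(truth, long, cohort)
        assert set(thinned["child_id"]) == set(cohort2["child_id"])
        assert len(cohort2) < len(cohort)


class TestStudyBundle:
    def test_simulate_study_consistent_keys(self, small_study):
        ids = set(small_study["cohort"]["child_id"])
        assert set(small_study["bmi"]["child_id"]) <= ids
        assert set(small_study["grs"]["child_id"]) == ids
        assert small_study["grs"]["scaled_score"].between(0, 10).all()

    def test_visit_count_near_nine_per_child(self, small_study):
        per_child = small_study["bmi"].groupby("child_id").size()
        assert 7.0 < per_child.mean() < 10.5
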