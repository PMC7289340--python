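"""Simulate a birth cohort with known ground truth.

Generates child-level covariates (sex, breastfeeding durations, five
confounders), a 94-SNP dosage matrix, and longitudinal BMI records from a
cubic-spline mixed model whose population curve peaks near 0.75 y and
rebounds near 5.5 y, then thins the records with covariate-dependent
(missing-at-random) dropout.
"""

from bmigrowth import default_truth, simulate_study

truth = default_truth(n_children=300, seed=1)
study = simulate_study(truth)

cohort, bmi = study["cohort"], study["bmi"]
print(f"children retained after dropout: {len(cohort)}")
print(f"BMI records: {len(bmi)} ({len(bmi) / len(cohort):.1f} per child)")
print(f"EBF months: mean {cohort['ebf_months'].mean():.2f}, "
      f"never-breastfed fraction {(cohort['ebf_months'] == 0).mean():.2f}")
print("\nmean BMI by age band (kg/m^2):")
bands = bmi.groupby(bmi["age_years"].round())["bmi"].agg(["mean", "count"])
print(bands.round(2).to_string())
# The age-0 mean sits near 14, rises to ~18 by age 1 (adiposity peak),
# dips to ~16 around ages 4-7 (adiposity rebound), then climbs through
# adolescence -- the canonical child BMI trajectory the model fits.
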