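# bmigrowth

Longitudinal modelling of child BMI from birth to age 18 as a function of
genetic risk and breastfeeding: a sex-specific weighted genetic risk score
(GRS), a cubic-spline linear mixed model with age × GRS × breastfeeding
interactions, contrast-based effect estimates at target ages, adiposity
peak/rebound timing with cluster-bootstrap inference, and the
"decile compensation" statistic that expresses a breastfeeding effect as
the genetic-risk increase it offsets.

The package is aimed at biostatisticians and genetic epidemiologists
working with birth-cohort growth data. Because such cohorts are
access-restricted, it ships a first-class synthetic cohort generator with
known ground truth, so every stage of the pipeline is testable end to end
without any data access.

## The model

For child *i* at age *t*, BMI is modelled (per sex) as

    y_ij = x(t_ij, G_i, E_i)'β + z(t_ij)'b_i + ε_ij,
    b_i ~ N(0, Σ_b),   ε_ij ~ N(0, σ²),

where the fixed-effect row contains a truncated-power cubic spline of age

    s(t) = (t, t², t³, (t−K₁)³₊, (t−K₂)³₊, (t−K₃)³₊),   K = (0.7, 1.5, 10) y,

main effects of the scaled GRS *G* and exclusive-breastfeeding duration
*E* (months), their product, the interactions s(t)×{G, E, G·E}, and
confounders (gestational age, maternal pre-pregnancy BMI, education,
smoking, income); random effects z(t) = (1, t, t²) have unstructured
covariance. Estimation is profiled ML/REML on per-child sufficient
statistics, which makes refitting a cluster-bootstrap resample a
millisecond-scale operation.

Key estimands, all linear contrasts L'β with Wald inference:

- **GRS effect**: BMI difference for +2.5 score units at a given age.
- **Breastfeeding effect**: BMI reduction from *m* months of (exclusive
  or any) breastfeeding at a given age and GRS level.
- **Compensation**: Δ = reduction / (per-unit GRS slope at E = 0), the
  GRS-unit ("decile") increase whose BMI effect the reduction offsets.
- **Adiposity peak (AP) / rebound (AR)**: stationary points of the fitted
  curve, exact quadratic roots of the piecewise-quadratic derivative of
  the truncated-power spline; shifts across settings get percentile
  cluster-bootstrap CIs (children resampled whole).

The GRS is Σᵢ βᵢ·dosageᵢ over 94 SNPs with sex-specific weights per
BMI-increasing allele, min–max scaled to 0–10 within sex; the
alleles-per-unit calibration (allele-count range / 10) converts score
units to unweighted risk-allele counts.

## Worked example

```python
from bmigrowth import build_design, default_truth, fit_design, simulate_study
from bmigrowth.effects import ebf_effect, grs_compensation, marginal_grs_effect

truth = default_truth(n_children=600, seed=4, sex_ratio=1.0)
study = simulate_study(truth)
model = fit_design(
    build_design(study["cohort"], study["grs"], study["bmi"], truth.model_spec), "reml"
)
for age in (7, 18):
    e = marginal_grs_effect(model, age)
    print(f"age {age}: +2.5 GRS units -> {e.estimate:.2f} kg/m^2")
comp = grs_compensation(model, 18.0, 7.5, 5.0)
print(f"5 months EBF at GRS 7.5 offsets {comp.delta_deciles:.1f} deciles")
```

prints (seed 4):

```
age 7: +2.5 GRS units -> 0.63 kg/m^2
age 18: +2.5 GRS units -> 2.25 kg/m^2
5 months EBF at GRS 7.5 offsets 3.8 deciles
```

The genetic effect on BMI grows with age, and at age 18 the BMI reduction
from five months of exclusive breastfeeding in the top GRS quartile is
equivalent to erasing ~4 deciles of genetic load. The `examples/`
directory has one short script per capability (simulation, GRS, model
fitting, contrasts, adiposity timing), and

```bash
bmigrowth run --config examples/demo_config.yaml
```

runs the whole pipeline (simulate → GRS → fit → effects → adiposity) on a
300-child cohort, writing `cohort.csv`, `grs.csv`, `model.json`,
`effects.csv`, `apar.csv`, a run log and a seed-stamped manifest.

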