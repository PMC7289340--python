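# Methods

This note records the statistical model, the synthetic study conditions,
the numerical choices, and the limitations a user should know before
trusting output on real data.

## Trajectory model

Per sex, BMI for child *i* at age *t* (years, domain [0, 20]) follows a
linear mixed model

    y_ij = x_ij'β + z_ij'b_i + ε_ij,   b_i ~ N(0, Σ_b),  ε_ij ~ N(0, σ²).

**Age basis.** A truncated-power cubic spline
`t, t², t³, (t−K₁)³₊, (t−K₂)³₊, (t−K₃)³₊` with default interior knots
(0.7, 1.5, 10) y. The basis is C² everywhere; its first derivative is
piecewise *quadratic*, which is why it was chosen over B-splines: the
adiposity peak and rebound of any fitted curve are closed-form roots of
per-piece quadratics, with no grid search and no tolerance stacking.
Basis columns are named `age, age2, age3, agek1, agek2, agek3`.

**Fixed effects.** Intercept; the six spline columns; the scaled genetic
risk score `grs` (0–10); the breastfeeding exposure (`ebf` or `bf`,
months, continuous — a continuous coding expresses the dose–response
behaviour of breastfeeding duration); their product `grs:ebf`; the
interaction of every spline column with each of {grs, ebf, grs·ebf}
(28 columns in total); plus confounders as main effects. Confounder
coding: treatment dummies against the largest category (education
reference `O_level`, smoking `Never`, income `lt400`) and mean-centered
continuous gestational age and maternal pre-pregnancy BMI. Contrast
estimands difference two population rows, so confounder columns cancel
exactly and never enter an estimate.

**Random effects.** Default {intercept, age, age²} per child with
unstructured covariance (configurable down to intercept-only). A
quadratic random slope is the smallest structure that lets within-child
BMI spread grow non-linearly from infancy to adolescence, as child BMI
data show.

**Estimation.** Profiled (restricted) maximum likelihood. Σ_b/σ² is
parameterised by its Cholesky factor, so it remains positive
semi-definite for every parameter value and boundary (singular) fits are
legal rather than errors. For fixed variance parameters, β and σ² have
closed-form profiled solutions via the Woodbury identity, leaving a
q(q+1)/2-dimensional smooth optimisation solved by L-BFGS-B with the
exact analytic gradient of the profiled deviance (Powell and a
diagonal-covariance retry as fallbacks). All likelihood evaluations run
on per-child sufficient statistics (Zᵢ'Zᵢ, Zᵢ'Xᵢ, Zᵢ'yᵢ, Xᵢ'Xᵢ, Xᵢ'yᵢ,
yᵢ'yᵢ), batched across children; a cluster-bootstrap refit is therefore a
re-indexing plus sums, a few milliseconds per resample. The fitter is
cross-checked in the test suite against a brute-force profile-likelihood
grid and against statsmodels MixedLM (log-likelihoods agree to ~1e-6).

Mixed-model likelihood inference remains valid when records are missing
at random, i.e. dropout depends only on observed covariates — exactly the
mechanism the synthetic generator uses.

**Numerical tolerances.** Relative deviance tolerance 1e-8, at most 500
iterations. Random-effect columns are standardised internally to their
root-mean-square so the variance parameters are comparably scaled.
Because the deviance valley is extremely flat near boundary fits,
coefficient estimates are reproducible under row permutation to about
1e-2 absolute — one to two orders of magnitude below their standard
errors — not to machine precision.

**Model selection.** Knot triples are chosen by BIC over a finite
candidate grid of ML fits (likelihoods comparable across fixed-effect
structures); interaction groups are then pruned by backward elimination
with likelihood-ratio tests at α = 0.05, respecting hierarchy (the
three-way group must leave before a two-way group is testable). The
winning specification is refit by REML. BIC-for-knots / LRT-for-terms is
a deliberate split: knot choice is a non-nested structural search where a
consistent criterion is wanted, term pruning is a nested hypothesis chain.

## Inference on contrasts

Single contrasts use z = L'β̂ / √(L'VL) with two-sided normal p-values and
±1.96·SE intervals; stacked contrasts use a chi-square Wald statistic
with df = rank(LVL'), falling back to a pseudo-inverse when the contrast
covariance is singular. No small-sample (Satterthwaite/Kenward–Roger)
correction is applied: the intended regime is hundreds to thousands of
children, where the large-sample reference is adequate — the type-I error
of the breastfeeding test at age 18 is verified in simulation to sit in a
binomial band around 5%. P-values are reported unadjusted for multiple
testing.

**Compensation.** The decile-compensation statistic divides the
breastfeeding BMI reduction at (age, GRS level) by the per-unit GRS slope
at the same age with breastfeeding fixed at zero — the no-breastfeeding
counterfactual slope. Because the model is linear in GRS, the resulting
Δ exactly solves predict(age, g+Δ, 0) = predict(age, g, 0) + reduction.
The slope must be positive; a non-positive slope raises an error rather
than reporting a meaningless negative compensation.

## Adiposity timing and the cluster bootstrap

Peak (AP) and rebound (AR) are located inside configurable search windows
— defaults (0.2, 2.0) y and (2.0, 10.0) y — by solving each derivative
piece's quadratic analytically and classifying roots by the second
derivative's sign; ties break to the smallest age, and absence of a
qualifying root is an explicit error. The root finder is verified against
a 1e-4-step grid search.

Timing shifts between settings get percentile 95% CIs from a cluster
bootstrap: children are resampled whole (all their observations) with
replacement to the original count, the *frozen* model specification is
refit on each resample (no re-selection; re-selection is available behind
a flag), and failed resamples (non-convergence, missing stationary point)
are recorded as NaN, excluded from the percentiles, and reported as a
failure count with a warning above a 20% failure rate. Percentile rather
than BCa intervals: at 150+ children the timing statistics are
near-symmetric and the simpler interval is stable at B in the low
hundreds. Empirical coverage for a true rebound shift of 0.5 y is
verified in simulation (B = 200; the default B for real analyses is
2,000).

## Genetic risk score

Weights are per BMI-increasing allele and sex-specific. A stored negative
weight means the listed allele is protective: at load time the weight is
negated and dosages are counted on the opposite allele (2 − d); male and
female weights must agree in sign. Raw scores Σ βᵢdᵢ are min–max scaled
to [0, 10] within sex, so 0 and 10 are attained exactly and one unit is
roughly one decile of the within-sex distribution. The alleles-per-unit
calibration is (allele-count range)/10 on the same children — consistent
with quoting a score range alongside an allele-count range. Scores are
affine-invariant in the raw weights and invariant to SNP column order.
Dosages can come from CSV or from a VCF (DS FORMAT field verbatim, hard
genotype calls otherwise).

The bundled 94-SNP weight panel is synthetic (gamma-distributed per-allele
weights on the GWAS meta-analysis scale, mild male/female heterogeneity,
uniform allele frequencies); it reproduces the distributional shape of
published panels — per-child risk-allele counts with mean in the 90s and a
range of several tens — but no real SNP identifiers, weights or LD.

## Synthetic study conditions

The generator emulates a UK birth cohort followed from birth to age 20:

- **Visit schedule** targets {0, 0.12, 0.83, 1.75, 4, 7, 8, 10, 12, 14,
  18} y with N(0, 0.1²) jitter truncated at 0 — dense in infancy, roughly
  annual later (~11 scheduled, ~9 retained per child after dropout).
- **Dropout**: each record kept with probability
  logistic(1.6 − 0.05·age + income-level offset) — retention falls with
  age and is lower in low-income strata. Missingness depends only on
  always-observed covariates (MAR by construction). Children losing all
  records are dropped from every table.
- **Exclusive breastfeeding**: mixture of a 30% never-breastfed point
  mass and a truncated-normal duration (mean 2.3, SD 1.4, max 6 months);
  any-breastfeeding adds an exponential(3-month) extension, capped at 24.
  Overall means ≈ 1.6 / 4.6 months.
- **Confounders**: independent categorical draws at realistic marginal
  proportions; gestational age N(39.5, 1.75²) weeks and maternal BMI
  N(23, 3.8²), both sample-centered. By default confounders have *no*
  causal effect on BMI (coefficients zero), so they exercise the design
  machinery without confounding the truth; effects can be switched on.
- **Genotypes**: 94 independent binomial(2, p) dosages at the panel's
  allele frequencies; optional truncated-normal dosage noise mimics
  imputation. No linkage disequilibrium.
- **BMI truth**: the same spline mixed-model family the fitting module
  estimates, so recovery is well-posed. The default coefficients are not
  hard-coded numbers but are solved at construction time from
  interpretable conditions: the reference curve (GRS 5, no breastfeeding)
  passes through 13.9 kg/m² at birth, peaks at exactly 18.0 kg/m² at
  0.75 y, rebounds at exactly 15.5 kg/m² at 5.5 y, and reaches 22.5 kg/m²
  at 18 y. The per-unit GRS curve is flat at the peak (no GRS effect on
  peak timing), slopes upward through the rebound (higher GRS → earlier
  rebound, ≈ −0.65 y across the interquartile GRS span) and yields
  quartile effects ≈ 0.6 kg/m² at 7 y and ≈ 2.0 kg/m² at 18 y. The
  breastfeeding curves rise through the peak and fall through the rebound
  (five months delays the peak ≈ 0.2 y and the rebound ≈ 0.7 y) with a
  protective effect that grows with age and GRS. Over-determined effect
  curves are solved by weighted least squares with heavy weight on the
  derivative conditions that control timing.
- **Random effects / residual**: SDs (0.9, 0.12, 0.006) for
  (intercept, age, age²) with correlations (−0.2, 0.1, −0.7), residual
  SD 0.8 kg/m² — marginal BMI SD grows from ≈ 1.4 at birth to ≈ 3.5 at
  18 y, matching the scale of observed growth data.

**Effect-size calibration.** The default gene–environment interaction is
sized so that the age-18 contrast "breastfeeding effect at GRS 7.5 minus
GRS 2.5" has a design z of ≈ 2.3 at 600 children (interaction value
−0.081 kg/m² per month per GRS unit at 18 y; total five-month reduction
1.5 kg/m² at GRS 5, at the upper end of effects reported for cohorts of
this kind). A consequence of concentrating the protection in high-GRS
children is that the breastfeeding *main* effect is slightly positive in
adolescence: at the lowest scores the model's five-month effect is small
and can be mildly adverse, a deliberate property of the default truth,
not an estimate about real children.

All randomness flows from the single truth seed through fixed per-stage
stream splits (cohort / BMI / missingness), so identical configuration
and seed reproduce byte-identical tables.

**What passing tests do and do not show.** The generator draws
independent SNPs, independent confounders, a shared visit template and
truly MAR dropout, and its truth lives inside the fitted model family.
Parameter recovery, calibrated type-I error and bootstrap coverage under
these conditions validate the estimation and inference machinery — they
do not certify behaviour under model misspecification, informative
dropout, LD between variants, or confounding structures absent from the
generator.

## Known limitations

- Sexes are fitted separately; there is no pooled model with sex
  interactions.
- Population-average AP/AR only; child-specific (random-effect) timing is
  out of scope.
- Wald inference without small-sample correction is anti-conservative
  below roughly a hundred children.
- The age domain is [0, 20]; no extrapolation is permitted, and contrast
  ages at the domain edge (18 y) rely on the sparser adolescent visits.
- The score-unit ↔ decile identification is approximate: min–max scaling
  makes one unit a tenth of the observed range, not exactly a tenth of
  the probability mass.
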