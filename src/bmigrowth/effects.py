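"""Contrast-based inference on fitted trajectory models.

All estimands are generalized linear hypotheses L'beta on the fixed effects:
the marginal genetic-risk-score effect at an age, the breastfeeding effect
at an age and GRS level, and the score-unit ("decile") compensation
equivalent of a breastfeeding effect. Because every contrast is a
difference of population design rows, confounder columns cancel and the
estimates do not depend on the confounder setting. Inference uses the
large-sample normal / chi-square Wald reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .design import population_row
from .lmm import FittedModel

__all__ = [
    "EffectEstimate",
    "CompensationResult",
    "glh_test",
    "marginal_grs_effect",
    "ebf_effect",
    "grs_compensation",
]


@dataclass
class EffectEstimate:
    """A single-contrast Wald result at a target age."""

    label: str
    age_years: float
    L: np.ndarray
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    covariate_setting: dict


@dataclass
class CompensationResult:
    """Breastfeeding effect expressed as an equivalent GRS-unit increase."""

    age_years: float
    grs_level: float
    ebf_months: float
    bmi_reduction: float
    grs_slope_ref: float  # kg/m^2 per score unit at zero breastfeeding
    delta_deciles: float


def glh_test(model: FittedModel, L: np.ndarray):
    """Wald test of one contrast (1-d ``L``) or several stacked rows (2-d).

    Single row: returns ``(estimate, se, z, p)`` with a two-sided normal p.
    Stacked rows: returns ``(estimates, chi2, df, p)``; a singular contrast
    covariance falls back to its pseudo-inverse with df = numerical rank.
    """
    L = np.asarray(L, dtype=float)
    beta = model.coef.to_numpy()
    V = model.vcov.to_numpy()
    if L.shape[-1] != len(beta):
        raise ValueError(f"contrast length {L.shape[-1]} != {len(beta)} coefficients")
    if L.ndim == 1:
        est = float(L @ beta)
        se = float(np.sqrt(max(L @ V @ L, 0.0)))
        if se == 0.0:
            z, p = 0.0, 1.0
        else:
            z = est / se
            p = 2.0 * sps.norm.sf(abs(z))
        return est, se, z, p
    est = L @ beta
    S = L @ V @ L.T
    rank = np.linalg.matrix_rank(S)
    if rank < S.shape[0]:
        import warnings

        warnings.warn("singular contrast covariance; using pseudo-inverse", stacklevel=2)
        Sinv = np.linalg.pinv(S)
    else:
        Sinv = np.linalg.inv(S)
    chi2 = float(est @ Sinv @ est)
    p = float(sps.chi2.sf(chi2, df=rank)) if rank > 0 else 1.0
    return est, chi2, int(rank), p


def _wald_row(model, L, label, age, setting) -> EffectEstimate:
    est, se, _, p = glh_test(model, L)
    return EffectEstimate(
        label=label,
        age_years=float(age),
        L=L,
        estimate=est,
        se=se,
        ci_low=est - 1.96 * se,
        ci_high=est + 1.96 * se,
        p_value=p,
        covariate_setting=dict(setting),
    )


def marginal_grs_effect(
    model: FittedModel,
    age: float,
    delta_grs: float = 2.5,
    ebf_fixed: float = 0.0,
) -> EffectEstimate:
    """Effect of a ``delta_grs``-unit GRS increase on BMI at ``age``.

    The model is linear in GRS, so the contrast does not depend on the
    baseline score, only on the age and the breastfeeding duration at which
    it is evaluated.
    """
    spec = _spec(model)
    hi = population_row(spec, age, grs=delta_grs, exposure_months=ebf_fixed)
    lo = population_row(spec, age, grs=0.0, exposure_months=ebf_fixed)
    return _wald_row(
        model,
        hi - lo,
        f"GRS +{delta_grs:g} units",
        age,
        {"delta_grs": delta_grs, "ebf_months": ebf_fixed},
    )


def ebf_effect(
    model: FittedModel,
    age: float,
    ebf_months: float,
    grs_level: float,
) -> EffectEstimate:
    """BMI reduction from ``ebf_months`` of the model's breastfeeding
    exposure, at ``age`` and ``grs_level``. Positive estimates mean the
    exposure lowers BMI."""
    spec = _spec(model)
    if spec.exposure is None:
        raise ValueError("model was fitted without a breastfeeding exposure")
    none = population_row(spec, age, grs=grs_level, exposure_months=0.0)
    fed = population_row(spec, age, grs=grs_level, exposure_months=float(ebf_months))
    return _wald_row(
        model,
        none - fed,
        f"{ebf_months:g} months {spec.exposure.upper()}",
        age,
        {"grs": grs_level, "months": ebf_months, "exposure": spec.exposure},
    )


def grs_compensation(
    model: FittedModel,
    age: float,
    grs_level: float,
    ebf_months: float,
) -> CompensationResult:
    """How many GRS units the breastfeeding effect at this age offsets.

    The reference slope is the per-unit GRS effect at zero breastfeeding,
    so ``delta_deciles`` solves
    ``predict(age, grs + delta, ebf=0) = predict(age, grs, ebf=0) + reduction``.
    """
    red = ebf_effect(model, age, ebf_months, grs_level).estimate
    slope = marginal_grs_effect(model, age, delta_grs=1.0, ebf_fixed=0.0).estimate
    if slope <= 0:
        raise ValueError(
            f"GRS slope at age {age} is {slope:.4g} <= 0; compensation undefined"
        )
    return CompensationResult(
        age_years=float(age),
        grs_level=float(grs_level),
        ebf_months=float(ebf_months),
        bmi_reduction=red,
        grs_slope_ref=slope,
        delta_deciles=red / slope,
    )


def _spec(model: FittedModel):
    if model.spec is None:
        raise ValueError("model carries no ModelSpec; refit via fit_design")
    return model.spec
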