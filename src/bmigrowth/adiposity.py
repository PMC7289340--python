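"""Adiposity peak / rebound timing and cluster-bootstrap inference.

On a truncated-power cubic spline the population-mean curve's first
derivative is piecewise quadratic, so the adiposity peak (local maximum of
BMI in infancy) and adiposity rebound (local minimum in childhood) are
roots of per-piece quadratics -- exact to floating precision, with no grid
search. Uncertainty comes from resampling whole children with replacement
(the cluster bootstrap), refitting the model with its specification frozen,
and recomputing the timing statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import ModelSpec, population_row
from .lmm import FittedModel, GroupStats, LmmError, fit_from_stats

__all__ = [
    "StationaryPointError",
    "ApArEstimate",
    "BootstrapResult",
    "find_stationary",
    "curve_stationary",
    "estimate_apar",
    "apar_shift",
    "cluster_bootstrap",
    "apar_shift_statistic",
]

AP_WINDOW = (0.2, 2.0)
AR_WINDOW = (2.0, 10.0)


class StationaryPointError(RuntimeError):
    pass


@dataclass
class ApArEstimate:
    """Population-average adiposity peak and rebound for one setting."""

    grs_level: float
    ebf_months: float
    age_at_ap: float
    bmi_at_ap: float
    age_at_ar: float
    bmi_at_ar: float
    ap_window: tuple = AP_WINDOW
    ar_window: tuple = AR_WINDOW


@dataclass
class BootstrapResult:
    statistic_label: str
    B: int
    samples: np.ndarray  # failures recorded as NaN
    ci_low: float
    ci_high: float
    n_failed: int
    seed: int

    @property
    def significant(self) -> bool:
        """Does the 95% percentile interval exclude zero?"""
        return bool(self.ci_low > 0.0 or self.ci_high < 0.0)


# ----------------------------------------------------------------------
# stationary points


def _coef_vector(spec: ModelSpec, coef) -> "np.ndarray":
    import pandas as pd

    if isinstance(coef, dict):
        coef = pd.Series(coef)
    return np.array([coef.get(c, 0.0) for c in spec.fixed_columns()])


def _curve_coefficients(spec: ModelSpec, coef, grs: float, ebf: float):
    """Collapse fixed effects to (constant, six spline coefs) for the
    population curve at one (GRS, breastfeeding) setting."""
    if spec is None:
        raise ValueError("model carries no ModelSpec")
    vec = _coef_vector(spec, coef)
    const = float(population_row(spec, 0.0, grs, ebf) @ vec)
    cols = spec.spline.column_names
    c = np.zeros(6)
    get = coef.get
    for j, s in enumerate(cols):
        val = get(s, 0.0)
        exp = spec.exposure
        if spec.include_grs:
            val += grs * get(f"{s}:grs", 0.0)
        if exp is not None:
            val += ebf * get(f"{s}:{exp}", 0.0)
            if spec.include_grs:
                val += grs * ebf * get(f"{s}:grs:{exp}", 0.0)
        c[j] = val
    return const, c


def _stationary_from_coefs(c: np.ndarray, knots, window, kind: str) -> float:
    """Smallest stationary age of the spline curve in ``window``.

    The derivative is c1 + 2 c2 t + 3 c3 t^2 + sum_k 3 c_{3+k} (t-K_k)^2
    for active knots; on each inter-knot piece this is a quadratic solved
    in closed form, classified by the sign of the second derivative.
    """
    lo, hi = window
    edges = sorted({lo, hi, *[k for k in knots if lo < k < hi]})
    roots = []
    for a, b in zip(edges[:-1], edges[1:]):
        active = [i for i, k in enumerate(knots) if k <= a + 1e-12]
        # expand derivative to q2 t^2 + q1 t + q0 on this piece
        q2 = 3.0 * c[2] + sum(3.0 * c[3 + i] for i in active)
        q1 = 2.0 * c[1] - sum(6.0 * c[3 + i] * knots[i] for i in active)
        q0 = c[0] + sum(3.0 * c[3 + i] * knots[i] ** 2 for i in active)
        if abs(q2) < 1e-14:
            cand = [] if abs(q1) < 1e-14 else [-q0 / q1]
        else:
            disc = q1 * q1 - 4.0 * q2 * q0
            if disc < 0:
                cand = []
            else:
                s = np.sqrt(disc)
                cand = [(-q1 - s) / (2.0 * q2), (-q1 + s) / (2.0 * q2)]
        for t in cand:
            if a - 1e-12 <= t <= b + 1e-12 and lo < t < hi:
                d2 = 2.0 * q2 * t + q1
                if (kind == "max" and d2 < 0) or (kind == "min" and d2 > 0):
                    roots.append(float(t))
    if not roots:
        raise StationaryPointError(
            f"no {'maximum' if kind == 'max' else 'minimum'} of the curve in "
            f"window ({lo}, {hi})"
        )
    roots.sort()
    dedup = [roots[0]]
    for r in roots[1:]:
        if r - dedup[-1] > 1e-9:
            dedup.append(r)
    return dedup[0]


def curve_stationary(
    spec: ModelSpec,
    coef,
    setting: dict | tuple,
    window: tuple,
    kind: str,
) -> tuple[float, float]:
    """Exact (age, bmi) stationary point of the population curve defined by
    a coefficient mapping -- fitted estimates or simulation ground truth."""
    if kind not in ("max", "min"):
        raise ValueError("kind must be 'max' or 'min'")
    grs, ebf = _setting(setting)
    lo, hi = window
    dom = spec.spline.age_domain
    if not (dom[0] <= lo < hi <= dom[1]):
        raise ValueError(f"window {window} outside the age domain {dom}")
    _, c = _curve_coefficients(spec, coef, grs, ebf)
    age = _stationary_from_coefs(c, spec.spline.knots, window, kind)
    bmi = float(population_row(spec, age, grs, ebf) @ _coef_vector(spec, coef))
    return age, bmi


def find_stationary(
    model: FittedModel,
    setting: dict | tuple,
    window: tuple,
    kind: str,
) -> tuple[float, float]:
    """Exact (age, bmi) of the fitted curve's stationary point of type
    ``kind`` ("max" for the adiposity peak, "min" for the rebound) inside
    ``window``, at a (grs, ebf) ``setting``."""
    return curve_stationary(model.spec, model.coef, setting, window, kind)


def estimate_apar(
    model: FittedModel,
    grs_level: float,
    ebf_months: float = 0.0,
    ap_window: tuple = AP_WINDOW,
    ar_window: tuple = AR_WINDOW,
) -> ApArEstimate:
    ap = find_stationary(model, (grs_level, ebf_months), ap_window, "max")
    ar = find_stationary(model, (grs_level, ebf_months), ar_window, "min")
    return ApArEstimate(
        grs_level=float(grs_level),
        ebf_months=float(ebf_months),
        age_at_ap=ap[0],
        bmi_at_ap=ap[1],
        age_at_ar=ar[0],
        bmi_at_ar=ar[1],
        ap_window=ap_window,
        ar_window=ar_window,
    )


def apar_shift(
    model: FittedModel,
    setting_a,
    setting_b,
    target: str = "AR",
    ap_window: tuple = AP_WINDOW,
    ar_window: tuple = AR_WINDOW,
) -> float:
    """Timing difference age(setting_a) - age(setting_b) in years for the
    peak (``target="AP"``) or rebound (``"AR"``); positive means setting_a
    reaches it later."""
    window, kind = {"AP": (ap_window, "max"), "AR": (ar_window, "min")}[target]
    age_a, _ = find_stationary(model, setting_a, window, kind)
    age_b, _ = find_stationary(model, setting_b, window, kind)
    return age_a - age_b


def _setting(setting) -> tuple[float, float]:
    if isinstance(setting, dict):
        return float(setting.get("grs", 0.0)), float(
            setting.get("ebf", setting.get("ebf_months", 0.0))
        )
    g, e = setting
    return float(g), float(e)


# ----------------------------------------------------------------------
# cluster bootstrap


def cluster_bootstrap(
    data: GroupStats,
    statistic_fn,
    B: int = 2000,
    seed: int = 0,
    label: str = "statistic",
) -> BootstrapResult:
    """Percentile bootstrap resampling whole children with replacement.

    ``data`` carries per-child model statistics; each iteration draws
    children to the original count, applies ``statistic_fn`` to the
    resampled data, and records failures (model non-convergence, missing
    stationary point) as NaN, excluded from the percentiles. Reproducible
    given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    G = data.n_groups
    samples = np.full(B, np.nan)
    for b in range(B):
        idx = rng.integers(0, G, size=G)
        try:
            samples[b] = float(statistic_fn(data.select(idx)))
        except (LmmError, StationaryPointError, np.linalg.LinAlgError, ValueError):
            pass
    ok = samples[~np.isnan(samples)]
    n_failed = B - len(ok)
    if len(ok) == 0:
        raise RuntimeError("every bootstrap iteration failed")
    if n_failed > 0.2 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap iterations failed; intervals may be unreliable",
            stacklevel=2,
        )
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return BootstrapResult(
        statistic_label=label,
        B=B,
        samples=samples,
        ci_low=float(lo),
        ci_high=float(hi),
        n_failed=int(n_failed),
        seed=int(seed),
    )


def apar_shift_statistic(
    spec: ModelSpec,
    setting_a,
    setting_b,
    target: str = "AR",
    estimation: str | None = None,
    ap_window: tuple = AP_WINDOW,
    ar_window: tuple = AR_WINDOW,
    theta0: np.ndarray | None = None,
):
    """Statistic closure for :func:`cluster_bootstrap`: refit the frozen
    model spec on the resample and return the requested timing shift.

    ``theta0`` (typically the full-data fit's ``theta``) warm-starts the
    variance-parameter optimisation of every resample fit.
    """
    est = estimation or spec.estimation

    def stat(stats: GroupStats) -> float:
        m = fit_from_stats(stats, estimation=est, spec=spec, theta0=theta0)
        if not m.converged:
            raise LmmError("resample fit did not converge")
        return apar_shift(m, setting_a, setting_b, target, ap_window, ar_window)

    return stat
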