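"""Truncated-power cubic spline basis for age trajectories.

The basis for a spline with interior knots (K1, K2, K3) on the age domain is

    t, t^2, t^3, (t - K1)^3_+, (t - K2)^3_+, (t - K3)^3_+

(no intercept column; the model supplies its own). A cubic truncated-power
basis is C^2 at every knot, and its first derivative is piecewise quadratic,
so stationary points of any fitted curve (adiposity peak and rebound) have
closed-form locations -- the reason this basis is used instead of B-splines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "spline_basis", "spline_basis_d1", "spline_basis_d2"]

#: stable design-column names for the six basis functions, in order
SPLINE_COLUMNS = ("age", "age2", "age3", "agek1", "agek2", "agek3")


@dataclass(frozen=True)
class SplineSpec:
    """Cubic truncated-power spline definition on an age domain in years."""

    knots: tuple[float, float, float] = (0.7, 1.5, 10.0)
    degree: int = 3
    age_domain: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        k = tuple(float(v) for v in self.knots)
        object.__setattr__(self, "knots", k)
        if len(k) != 3 or not (k[0] < k[1] < k[2]):
            raise ValueError(f"knots must be three strictly increasing ages, got {k}")
        if k[0] <= self.age_domain[0]:
            raise ValueError(f"first knot {k[0]} must exceed the domain start")
        if k[2] > self.age_domain[1]:
            raise ValueError(f"last knot {k[2]} exceeds the age domain {self.age_domain}")
        if self.degree != 3:
            raise ValueError("only cubic (degree 3) splines are supported")

    @property
    def column_names(self) -> tuple[str, ...]:
        return SPLINE_COLUMNS

    @property
    def n_columns(self) -> int:
        return 6


def _check_domain(ages: np.ndarray, spec: SplineSpec) -> np.ndarray:
    t = np.asarray(ages, dtype=float)
    lo, hi = spec.age_domain
    bad = (t < lo) | (t > hi) | ~np.isfinite(t)
    if bad.any():
        off = t.ravel()[np.flatnonzero(np.atleast_1d(bad).ravel())[0]]
        raise ValueError(
            f"age {off} outside the spline domain [{lo}, {hi}]; no extrapolation"
        )
    return t


def spline_basis(ages, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Evaluate the six basis functions at ``ages`` (exact closed form)."""
    t = _check_domain(ages, spec)
    k1, k2, k3 = spec.knots
    cols = [
        t,
        t**2,
        t**3,
        np.clip(t - k1, 0.0, None) ** 3,
        np.clip(t - k2, 0.0, None) ** 3,
        np.clip(t - k3, 0.0, None) ** 3,
    ]
    return np.stack(cols, axis=-1)


def spline_basis_d1(ages, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """First derivative of each basis column: piecewise quadratic in age."""
    t = _check_domain(ages, spec)
    k1, k2, k3 = spec.knots
    cols = [
        np.ones_like(t),
        2.0 * t,
        3.0 * t**2,
        3.0 * np.clip(t - k1, 0.0, None) ** 2,
        3.0 * np.clip(t - k2, 0.0, None) ** 2,
        3.0 * np.clip(t - k3, 0.0, None) ** 2,
    ]
    return np.stack(cols, axis=-1)


def spline_basis_d2(ages, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Second derivative of each basis column: piecewise linear, continuous."""
    t = _check_domain(ages, spec)
    k1, k2, k3 = spec.knots
    cols = [
        np.zeros_like(t),
        2.0 * np.ones_like(t),
        6.0 * t,
        6.0 * np.clip(t - k1, 0.0, None),
        6.0 * np.clip(t - k2, 0.0, None),
        6.0 * np.clip(t - k3, 0.0, None),
    ]
    return np.stack(cols, axis=-1)
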