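"""Fixed- and random-effect design matrices for the trajectory model.

The fixed-effect design is

    1 + spline(age) + GRS + EXP + GRS*EXP
      + spline(age) x GRS + spline(age) x EXP + spline(age) x GRS*EXP
      + confounders

where EXP is the breastfeeding exposure (exclusive ``ebf`` or any ``bf``,
months, continuous) and GRS the 0-10 scaled genetic risk score. Confounders
enter as main effects only: treatment-coded dummies against the largest
category for the factors, and mean-centered continuous covariates. Random
effects per child are a subset of {intercept, age, age^2} with unstructured
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import SplineSpec, spline_basis

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "build_design",
    "population_row",
    "population_rows",
]

# factor codings; reference = level with the largest cohort proportion
EDUCATION_LEVELS = ("CSE_none", "Vocational", "O_level", "A_level", "Degree")
SMOKING_LEVELS = ("Never", "Not_during_pregnancy", "During_pregnancy")
INCOME_LEVELS = ("lt100", "lt200", "lt300", "lt400", "ge400")

FACTOR_CODINGS: dict[str, tuple[tuple[str, ...], str]] = {
    "education": (EDUCATION_LEVELS, "O_level"),
    "smoking": (SMOKING_LEVELS, "Never"),
    "income": (INCOME_LEVELS, "lt400"),
}
CONTINUOUS_CONFOUNDERS = ("gestational_age_c", "maternal_bmi_c")
DEFAULT_CONFOUNDERS = (
    "education",
    "smoking",
    "income",
    "gestational_age_c",
    "maternal_bmi_c",
)

RANDOM_TERMS = ("intercept", "age", "age2")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one sex-specific trajectory model."""

    spline: SplineSpec = SplineSpec()
    exposure: str | None = "ebf"  # "ebf", "bf", or None
    include_grs: bool = True
    #: which exposure terms interact with every spline column
    interactions: tuple[str, ...] = ("grs", "exposure", "grs:exposure")
    confounders: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ("intercept", "age", "age2")
    estimation: str = "reml"

    def __post_init__(self) -> None:
        if self.exposure not in (None, "ebf", "bf"):
            raise ValueError(f"exposure must be 'ebf', 'bf' or None, got {self.exposure!r}")
        for term in self.interactions:
            if term not in ("grs", "exposure", "grs:exposure"):
                raise ValueError(f"unknown interaction term {term!r}")
            if term in ("grs", "grs:exposure") and not self.include_grs:
                raise ValueError(f"interaction {term!r} requires include_grs=True")
            if term in ("exposure", "grs:exposure") and self.exposure is None:
                raise ValueError(f"interaction {term!r} requires an exposure")
        for c in self.confounders:
            if c not in FACTOR_CODINGS and c not in CONTINUOUS_CONFOUNDERS:
                raise ValueError(f"unknown confounder {c!r}")
        for r in self.random_terms:
            if r not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {r!r}; choose from {RANDOM_TERMS}")
        if self.estimation not in ("ml", "reml"):
            raise ValueError("estimation must be 'ml' or 'reml'")

    # ------------------------------------------------------------------
    @property
    def exposure_column(self) -> str | None:
        return self.exposure

    def fixed_columns(self) -> list[str]:
        """Deterministic ordering of fixed-effect design columns."""
        cols = ["Intercept", *self.spline.column_names]
        exp = self.exposure
        if self.include_grs:
            cols.append("grs")
        if exp is not None:
            cols.append(exp)
        if self.include_grs and exp is not None:
            cols.append(f"grs:{exp}")
        for term in self.interactions:
            name = {"grs": "grs", "exposure": exp, "grs:exposure": f"grs:{exp}"}[term]
            cols.extend(f"{s}:{name}" for s in self.spline.column_names)
        for c in self.confounders:
            if c in FACTOR_CODINGS:
                levels, ref = FACTOR_CODINGS[c]
                cols.extend(f"{c}[{lv}]" for lv in levels if lv != ref)
            else:
                cols.append(c)
        return cols

    def replace(self, **kw) -> "ModelSpec":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class DesignMatrices:
    """Assembled design: fixed X, per-child random Z, outcome y, child labels."""

    X: np.ndarray
    Z: np.ndarray | None
    y: np.ndarray
    group_labels: np.ndarray  # one child id per row of X
    columns: list[str]
    re_names: list[str]
    spec: ModelSpec


def _factor_dummies(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    levels, ref = FACTOR_CODINGS[name]
    vals = values.astype(str).to_numpy()
    unknown = set(vals) - set(levels)
    if unknown:
        raise ValueError(
            f"unknown {name} level {sorted(unknown)[0]!r}; expected one of {levels}"
        )
    keep = [lv for lv in levels if lv != ref]
    mat = np.stack([(vals == lv).astype(float) for lv in keep], axis=-1)
    return mat, [f"{name}[{lv}]" for lv in keep]


def _exposure_values(cohort_row: pd.DataFrame, exposure: str) -> np.ndarray:
    col = {"ebf": "ebf_months", "bf": "bf_months"}[exposure]
    if col not in cohort_row.columns:
        raise ValueError(f"cohort table lacks column {col!r} for exposure {exposure!r}")
    return cohort_row[col].to_numpy(dtype=float)


def _core_block(
    ages: np.ndarray, grs: np.ndarray, exp_months: np.ndarray | None, spec: ModelSpec
) -> list[np.ndarray]:
    """Intercept, spline, exposure main effects and spline interactions."""
    B = spline_basis(ages, spec.spline)
    blocks = [np.ones((len(ages), 1)), B]
    exp = spec.exposure
    if spec.include_grs:
        blocks.append(grs[:, None])
    if exp is not None:
        blocks.append(exp_months[:, None])
    if spec.include_grs and exp is not None:
        blocks.append((grs * exp_months)[:, None])
    for term in spec.interactions:
        mod = {"grs": grs, "exposure": exp_months, "grs:exposure": None}[term]
        if mod is None:
            mod = grs * exp_months
        blocks.append(B * mod[:, None])
    return blocks


def build_design(
    cohort: pd.DataFrame,
    grs: pd.DataFrame,
    long: pd.DataFrame,
    spec: ModelSpec,
) -> DesignMatrices:
    """Join the tables on ``child_id`` and assemble (X, Z, y, groups).

    ``grs`` needs columns ``child_id`` and ``scaled_score``; ``long`` needs
    ``child_id, age_years, bmi``. Children present in ``long`` must all be
    present in the other two tables.
    """
    cohort = cohort.set_index("child_id") if "child_id" in cohort.columns else cohort
    g = grs.set_index("child_id") if "child_id" in grs.columns else grs
    missing = set(long["child_id"]) - set(cohort.index)
    if missing:
        raise ValueError(f"children in BMI table missing from cohort table: {sorted(missing)[:5]}")
    if spec.include_grs:
        missing_g = set(long["child_id"]) - set(g.index)
        if missing_g:
            raise ValueError(f"children missing a GRS value: {sorted(missing_g)[:5]}")

    rows = cohort.loc[long["child_id"]]
    ages = long["age_years"].to_numpy(dtype=float)
    y = long["bmi"].to_numpy(dtype=float)
    grs_vals = (
        g.loc[long["child_id"], "scaled_score"].to_numpy(dtype=float)
        if spec.include_grs
        else np.zeros(len(ages))
    )
    exp_vals = _exposure_values(rows, spec.exposure) if spec.exposure else None

    blocks = _core_block(ages, grs_vals, exp_vals, spec)
    for c in spec.confounders:
        if c in FACTOR_CODINGS:
            mat, _ = _factor_dummies(rows[c], c)
            blocks.append(mat)
        else:
            blocks.append(rows[c].to_numpy(dtype=float)[:, None])
    X = np.concatenate(blocks, axis=1)
    columns = spec.fixed_columns()
    assert X.shape[1] == len(columns)

    Z, re_names = _random_design(ages, spec.random_terms)
    return DesignMatrices(
        X=X,
        Z=Z,
        y=y,
        group_labels=long["child_id"].to_numpy(),
        columns=columns,
        re_names=re_names,
        spec=spec,
    )


def _random_design(ages: np.ndarray, random_terms) -> tuple[np.ndarray | None, list[str]]:
    if not random_terms:
        return None, []
    cols = {"intercept": np.ones_like(ages), "age": ages, "age2": ages**2}
    Z = np.stack([cols[r] for r in random_terms], axis=-1)
    return Z, list(random_terms)


def population_rows(
    spec: ModelSpec, ages, grs: float = 0.0, exposure_months: float = 0.0
) -> np.ndarray:
    """Fixed-effect design rows for the population-average child at a
    vector of ages, with GRS and breastfeeding held fixed.

    Confounders are held at their reference setting (factor dummies 0,
    centered continuous covariates 0), so differences of such rows cancel
    every confounder column -- the basis of all contrast estimands.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    g = np.full(len(ages), float(grs))
    e = np.full(len(ages), float(exposure_months)) if spec.exposure else None
    blocks = _core_block(ages, g, e, spec)
    n_conf = len(spec.fixed_columns()) - sum(b.shape[1] for b in blocks)
    blocks.append(np.zeros((len(ages), n_conf)))
    return np.concatenate(blocks, axis=1)


def population_row(
    spec: ModelSpec, age: float, grs: float = 0.0, exposure_months: float = 0.0
) -> np.ndarray:
    """One population-average design row; see :func:`population_rows`."""
    return population_rows(spec, [age], grs, exposure_months)[0]
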