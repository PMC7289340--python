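"""Readers and writers for the pipeline's tabular and JSON artifacts.

All tables are plain comma-separated UTF-8 files with a mandatory header
row and ``.`` decimals. Readers validate the header exactly and
range-check every value, reporting the first violation with its row
number, column and offending value. Genotypes may alternatively come from
a VCF, taking per-sample dosages from the DS FORMAT field when present and
counted alternate alleles otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import FACTOR_CODINGS, ModelSpec
from .lmm import FittedModel
from .splines import SplineSpec

__all__ = [
    "read_cohort",
    "read_bmi_long",
    "read_dosages",
    "read_weights",
    "read_vcf_dosages",
    "write_table",
    "save_model",
    "load_model",
    "save_truth",
    "load_truth",
]

COHORT_COLUMNS = [
    "child_id", "sex", "ebf_months", "bf_months", "gestational_age_c",
    "maternal_bmi_c", "education", "smoking", "income",
]
BMI_COLUMNS = ["child_id", "age_years", "bmi"]
WEIGHT_COLUMNS = ["snp_id", "effect_allele", "weight_male", "weight_female"]


class SchemaError(ValueError):
    pass


def _check_header(df: pd.DataFrame, expected: list[str], path, prefix: bool = False) -> None:
    found = list(df.columns)
    ok = found[: len(expected)] == expected if prefix else found == expected
    if not ok:
        raise SchemaError(
            f"{path}: malformed header; expected columns {expected}"
            f"{' (leading)' if prefix else ''}, found {found}"
        )


def _check_range(df: pd.DataFrame, col: str, lo, hi, path) -> None:
    v = pd.to_numeric(df[col], errors="coerce")
    bad = v.isna() | (v < lo) | (v > hi)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: row {i + 2}, column {col!r}: value {df[col].iloc[i]!r} "
            f"outside [{lo}, {hi}]"
        )


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, COHORT_COLUMNS, path)
    if df["child_id"].duplicated().any():
        dup = df.loc[df["child_id"].duplicated(), "child_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate child_id {dup!r}")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        i = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise SchemaError(f"{path}: row {i + 2}, column 'sex': {df['sex'].iloc[i]!r}")
    _check_range(df, "ebf_months", 0.0, 24.0, path)
    _check_range(df, "bf_months", 0.0, 24.0, path)
    short = df["bf_months"] < df["ebf_months"] - 1e-9
    if short.any():
        i = int(np.flatnonzero(short.to_numpy())[0])
        raise SchemaError(
            f"{path}: row {i + 2}: bf_months {df['bf_months'].iloc[i]} < "
            f"ebf_months {df['ebf_months'].iloc[i]}"
        )
    for name, (levels, _) in FACTOR_CODINGS.items():
        bad = ~df[name].isin(levels)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: row {i + 2}, column {name!r}: {df[name].iloc[i]!r} "
                f"not in {levels}"
            )
    return df


def read_bmi_long(path, age_max: float = 20.0) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, BMI_COLUMNS, path)
    _check_range(df, "age_years", 0.0, age_max, path)
    v = pd.to_numeric(df["bmi"], errors="coerce")
    bad = v.isna() | (v <= 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: row {i + 2}, column 'bmi': value {df['bmi'].iloc[i]!r} must be > 0"
        )
    return df


def read_dosages(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, ["child_id"], path, prefix=True)
    for col in df.columns[1:]:
        _check_range(df, col, 0.0, 2.0, path)
    return df


def read_weights(path) -> pd.DataFrame:
    from .grs import load_weight_table

    df = pd.read_csv(path)
    _check_header(df, WEIGHT_COLUMNS, path, prefix=True)
    return load_weight_table(df)


def read_vcf_dosages(path) -> pd.DataFrame:
    """Child x SNP alternate-allele dosages from a VCF.

    The DS FORMAT field is used verbatim when present; otherwise hard
    genotype calls are converted to 0/1/2 alternate-allele counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            cols[vid] = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = np.asarray([sum(1 for a in g[:-1] if a > 0) for g in var.genotypes], dtype=float)
            cols[vid] = gts
    vcf.close()
    out = pd.DataFrame(cols)
    out.insert(0, "child_id", samples)
    return out


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ----------------------------------------------------------------------
# model / truth JSON


def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "knots": list(spec.spline.knots),
        "age_domain": list(spec.spline.age_domain),
        "exposure": spec.exposure,
        "include_grs": spec.include_grs,
        "interactions": list(spec.interactions),
        "confounders": list(spec.confounders),
        "random_terms": list(spec.random_terms),
        "estimation": spec.estimation,
    }


def _spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        spline=SplineSpec(knots=tuple(d["knots"]), age_domain=tuple(d["age_domain"])),
        exposure=d["exposure"],
        include_grs=d["include_grs"],
        interactions=tuple(d["interactions"]),
        confounders=tuple(d["confounders"]),
        random_terms=tuple(d["random_terms"]),
        estimation=d["estimation"],
    )


def save_model(model: FittedModel, path, stamp: dict | None = None) -> Path:
    payload = {
        "columns": model.columns,
        "coef": [float(v) for v in model.coef],
        "vcov": model.vcov.to_numpy().tolist(),
        "re_names": model.re_names,
        "re_cov": np.asarray(model.re_cov).tolist(),
        "sigma2": model.sigma2,
        "loglik": model.loglik,
        "method": model.method,
        "converged": model.converged,
        "n_children": model.n_children,
        "n_obs": model.n_obs,
        "message": model.message,
        "spec": None if model.spec is None else _spec_to_dict(model.spec),
    }
    if stamp:
        payload["stamp"] = stamp
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_model(path) -> FittedModel:
    d = json.loads(Path(path).read_text())
    cols = d["columns"]
    return FittedModel(
        coef=pd.Series(d["coef"], index=cols),
        vcov=pd.DataFrame(np.asarray(d["vcov"]), index=cols, columns=cols),
        re_cov=np.asarray(d["re_cov"]),
        re_names=list(d["re_names"]),
        sigma2=float(d["sigma2"]),
        loglik=float(d["loglik"]),
        method=d["method"],
        converged=bool(d["converged"]),
        n_children=int(d["n_children"]),
        n_obs=int(d["n_obs"]),
        spec=None if d.get("spec") is None else _spec_from_dict(d["spec"]),
        message=d.get("message", ""),
    )


def save_truth(truth, path, stamp: dict | None = None) -> Path:
    d = dataclasses.asdict(truth)
    d["allele_freqs"] = np.asarray(d["allele_freqs"]).tolist()
    d["random_effect_corr"] = np.asarray(d["random_effect_corr"]).tolist()
    d["model_spec"] = _spec_to_dict(truth.model_spec)
    if stamp:
        d["stamp"] = stamp
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(d, indent=1))
    return path


def load_truth(path):
    from .simulate import SimulationTruth

    d = json.loads(Path(path).read_text())
    d.pop("stamp", None)
    d["model_spec"] = _spec_from_dict(d["model_spec"])
    d["allele_freqs"] = np.asarray(d["allele_freqs"])
    d["random_effect_corr"] = np.asarray(d["random_effect_corr"])
    for k in ("random_effect_sd", "visit_schedule"):
        d[k] = tuple(d[k])
    return SimulationTruth(**d)
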