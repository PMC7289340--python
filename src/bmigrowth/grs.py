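"""Sex-specific weighted genetic risk scores (GRS).

The raw score for a child is the dosage-weighted sum over SNPs,
``sum_i beta_i * d_i``, using the weight column of the child's sex, with
every SNP oriented so its weight refers to the BMI-increasing allele
(a stored negative weight means the listed allele is protective: the weight
is negated and dosages are counted on the opposite allele, ``2 - d``).

Raw scores are then min-max scaled per sex to the range 0-10, so one unit
is approximately one decile of the within-sex score distribution. The
``alleles_per_unit`` calibration converts score units back to unweighted
risk-allele counts: the within-sex allele-count range divided by the 10
score units it spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "load_weight_table",
    "compute_raw_score",
    "scale_scores",
    "build_grs",
    "synthetic_weight_table",
]

VALID_ALLELES = {"A", "C", "G", "T"}
WEIGHT_COLUMNS = ["snp_id", "effect_allele", "weight_male", "weight_female"]


def load_weight_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and orient a SNP weight table.

    Returns a copy with all weights >= 0 and a boolean ``flipped`` column
    marking SNPs whose stored weights were negative (their dosages must be
    counted on the opposite allele). Sexes must agree on the direction.
    """
    missing = [c for c in WEIGHT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"weight table lacks columns {missing}; expected {WEIGHT_COLUMNS}")
    t = table.copy().reset_index(drop=True)
    if t["snp_id"].duplicated().any():
        dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r} in weight table")
    bad = set(t["effect_allele"].astype(str)) - VALID_ALLELES
    if bad:
        raise ValueError(f"invalid effect allele {sorted(bad)[0]!r}; must be one of A,C,G,T")
    wm = t["weight_male"].to_numpy(dtype=float)
    wf = t["weight_female"].to_numpy(dtype=float)
    disagree = (wm * wf) < 0
    if disagree.any():
        snp = t.loc[np.flatnonzero(disagree)[0], "snp_id"]
        raise ValueError(
            f"male and female weights disagree in sign for {snp!r}; cannot orient"
        )
    flipped = (wm < 0) | (wf < 0)
    t["weight_male"] = np.abs(wm)
    t["weight_female"] = np.abs(wf)
    t["flipped"] = flipped
    return t


def _oriented_dosages(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Align dosage columns to weight rows and flip where needed."""
    w = weights if "flipped" in weights.columns else load_weight_table(weights)
    snp_ids = list(w["snp_id"])
    missing = [s for s in snp_ids if s not in dosages.columns]
    extra = [c for c in dosages.columns if c not in snp_ids and c != "child_id"]
    if missing or extra:
        raise ValueError(
            f"dosage/weight SNP mismatch; missing from dosages: {missing[:5]}, "
            f"unmatched dosage columns: {extra[:5]}"
        )
    d = dosages.set_index("child_id") if "child_id" in dosages.columns else dosages
    d = d[snp_ids]
    if d.isna().any().any():
        col = d.columns[d.isna().any().to_numpy()][0]
        raise ValueError(f"missing dosage cells in column {col!r}; impute upstream")
    vals = d.to_numpy(dtype=float)
    flip = w["flipped"].to_numpy()
    vals = np.where(flip[None, :], 2.0 - vals, vals)
    return pd.DataFrame(vals, index=d.index, columns=snp_ids)


def compute_raw_score(
    dosages: pd.DataFrame, weights: pd.DataFrame, sex_map: pd.Series
) -> pd.Series:
    """Per-child raw score, using the weight column of each child's sex."""
    w = weights if "flipped" in weights.columns else load_weight_table(weights)
    d = _oriented_dosages(dosages, w)
    sex = sex_map.reindex(d.index)
    if sex.isna().any():
        child = sex.index[sex.isna().to_numpy()][0]
        raise ValueError(f"no sex recorded for child {child!r}")
    bad = set(sex) - {"male", "female"}
    if bad:
        raise ValueError(f"invalid sex value {sorted(bad)[0]!r}")
    wmat = np.where(
        (sex == "male").to_numpy()[:, None],
        w["weight_male"].to_numpy()[None, :],
        w["weight_female"].to_numpy()[None, :],
    )
    raw = (d.to_numpy() * wmat).sum(axis=1)
    return pd.Series(raw, index=d.index, name="raw_score")


def scale_scores(
    raw_scores: pd.Series, sex_map: pd.Series, allele_counts: pd.Series | None = None
) -> pd.DataFrame:
    """Min-max scale raw scores to [0, 10] within each sex.

    If per-child unweighted risk-allele counts are supplied, the per-sex
    ``alleles_per_unit`` calibration (allele-count range / 10) is attached.
    """
    sex = sex_map.reindex(raw_scores.index)
    out = pd.DataFrame(
        {"sex": sex, "raw_score": raw_scores, "scaled_score": np.nan}, index=raw_scores.index
    )
    out["alleles_per_unit"] = np.nan
    for s, idx in out.groupby("sex").groups.items():
        r = raw_scores.loc[idx]
        if len(idx) < 2:
            raise ValueError(f"need at least two {s} children to scale scores")
        lo, hi = float(r.min()), float(r.max())
        if hi == lo:
            raise ValueError(f"all raw scores identical for sex {s!r}; scaling undefined")
        out.loc[idx, "scaled_score"] = 10.0 * (r - lo) / (hi - lo)
        if allele_counts is not None:
            c = allele_counts.loc[idx]
            out.loc[idx, "alleles_per_unit"] = (float(c.max()) - float(c.min())) / 10.0
    out.index.name = "child_id"
    return out


def build_grs(
    dosages: pd.DataFrame, weights: pd.DataFrame, sex_map: pd.Series
) -> pd.DataFrame:
    """Raw + scaled GRS with allele-count calibration, one row per child."""
    w = weights if "flipped" in weights.columns else load_weight_table(weights)
    raw = compute_raw_score(dosages, w, sex_map)
    counts = _oriented_dosages(dosages, w).sum(axis=1)
    res = scale_scores(raw, sex_map, allele_counts=counts)
    res["risk_alleles"] = counts
    return res.reset_index()


def synthetic_weight_table(n_snps: int = 94, seed: int = 20200611) -> pd.DataFrame:
    """A synthetic stand-in for the published 94-SNP weight panel.

    Per-allele weights (kg/m^2) are drawn on the scale of genome-wide
    association meta-analysis effect sizes for adult BMI, with mild
    male/female heterogeneity; allele frequencies are attached for use by
    the cohort simulator. Purely synthetic: the published panel is not
    redistributed here.
    """
    rng = np.random.default_rng(seed)
    base = rng.gamma(shape=2.2, scale=0.014, size=n_snps) + 0.005
    ratio = np.exp(rng.normal(0.0, 0.15, size=n_snps))
    freqs = rng.uniform(0.08, 0.92, size=n_snps)
    alleles = rng.choice(list("ACGT"), size=n_snps)
    t = pd.DataFrame(
        {
            "snp_id": [f"rs{100000 + 137 * i}" for i in range(n_snps)],
            "effect_allele": alleles,
            "weight_male": base,
            "weight_female": base * ratio,
            "allele_freq": freqs,
        }
    )
    return t
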