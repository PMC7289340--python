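"""End-to-end pipeline: simulate/load -> GRS -> fit -> effects -> adiposity.

A run is fully described by a :class:`PipelineConfig` (deserialisable from
YAML) plus its single seed; per-stage random streams are split
deterministically from that seed, so identical config + seed reproduce
byte-identical tables. Every artifact set is accompanied by a manifest
carrying the config hash and seed. A failing stage renames the artifacts
written so far with a ``.partial`` suffix and aborts with a stage-named
error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .adiposity import (
    apar_shift_statistic,
    cluster_bootstrap,
    estimate_apar,
)
from .design import ModelSpec, build_design
from .effects import ebf_effect, grs_compensation, marginal_grs_effect
from .grs import build_grs, synthetic_weight_table
from .lmm import FittedModel, GroupStats, fit_from_stats
from .selection import select_model
from .simulate import default_truth, simulate_study
from .splines import SplineSpec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_SIMULATE_KEYS = {
    "n_children", "sex_ratio", "residual_sd", "random_effect_sd", "ebf_dist",
    "bf_extension_mean", "visit_schedule", "visit_jitter_sd", "dosage_noise",
}


@dataclass
class PipelineConfig:
    """Validated, fully serialisable description of one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    sex: str = "male"
    simulate: dict | None = field(default_factory=lambda: {"n_children": 300})
    inputs: dict | None = None  # paths: cohort, bmi, dosages|vcf, weights
    knots: tuple = (0.7, 1.5, 10.0)
    select_knots: list | None = None  # optional grid of knot triples
    exposure: str = "ebf"
    confounders: tuple = ()
    random_terms: tuple = ("intercept", "age", "age2")
    estimation: str = "reml"
    ages: tuple = (7.0, 10.0, 15.0, 18.0)
    grs_levels: tuple = (2.5, 5.0, 7.5)
    ebf_levels: tuple = (3.0, 5.0)
    bootstrap_B: int = 200
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.exposure not in ("ebf", "bf"):
            raise ValueError(f"exposure must be 'ebf' or 'bf', got {self.exposure!r}")
        if self.simulate is None and self.inputs is None:
            raise ValueError("either 'simulate' or 'inputs' must be given")
        if self.simulate is not None:
            unknown = set(self.simulate) - _SIMULATE_KEYS
            if unknown:
                raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        if self.bootstrap_B < 0:
            raise ValueError("bootstrap_B must be >= 0")
        SplineSpec(knots=tuple(self.knots))  # validates ordering/domain

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            spline=SplineSpec(knots=tuple(self.knots)),
            exposure=self.exposure,
            confounders=tuple(self.confounders),
            random_terms=tuple(self.random_terms),
            estimation=self.estimation,
        )

    def stage_seed(self, stage: str) -> int:
        order = ("simulate", "bootstrap")
        ss = np.random.SeedSequence(
            entropy=int(self.seed) % (2**31), spawn_key=(order.index(stage),)
        )
        return int(ss.generate_state(1)[0] % (2**31))


def _setup_log(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("bmigrowth")
    root.addHandler(handler)
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the result bundle (paths and objects)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    handler = _setup_log(out, config.log_level)
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        stage = "simulate" if config.simulate is not None else "read_inputs"
        if config.simulate is not None:
            sim = dict(config.simulate)
            n = int(sim.pop("n_children", 300))
            truth = default_truth(n_children=n, seed=config.stage_seed("simulate"), **sim)
            study = simulate_study(truth)
            cohort, dosages, bmi = study["cohort"], study["dosages"], study["bmi"]
            grs_table = study["grs"]
            written.append(bio.write_table(cohort, out / "cohort.csv"))
            written.append(bio.write_table(bmi, out / "bmi_long.csv"))
            written.append(bio.write_table(dosages, out / "dosages.csv"))
            written.append(bio.save_truth(truth, out / "truth.json", stamp=stamp))
            weights = synthetic_weight_table(n_snps=len(truth.allele_freqs))
        else:
            paths = config.inputs or {}
            for key in ("cohort", "bmi", "weights"):
                if key not in paths:
                    raise FileNotFoundError(f"inputs.{key} not configured")
            for key, p in paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p} (inputs.{key})")
            cohort = bio.read_cohort(paths["cohort"])
            bmi = bio.read_bmi_long(paths["bmi"])
            weights = bio.read_weights(paths["weights"])
            if "vcf" in paths:
                dosages = bio.read_vcf_dosages(paths["vcf"])
            else:
                dosages = bio.read_dosages(paths["dosages"])
            grs_table = None
        logger.info("inputs ready: %d children, %d BMI records", len(cohort), len(bmi))

        # ------------------------------------------------ grs
        stage = "grs"
        if grs_table is None:
            grs_table = build_grs(dosages, weights, cohort.set_index("child_id")["sex"])
        written.append(bio.write_table(
            grs_table[["child_id", "sex", "raw_score", "scaled_score"]], out / "grs.csv"
        ))

        # ------------------------------------------------ fit
        stage = "fit"
        keep = cohort["sex"] == config.sex
        cohort_s = cohort.loc[keep].reset_index(drop=True)
        bmi_s = bmi[bmi["child_id"].isin(set(cohort_s["child_id"]))].reset_index(drop=True)
        spec = config.model_spec()
        if config.select_knots:
            sel = select_model(cohort_s, grs_table, bmi_s, config.select_knots, base_spec=spec)
            spec, model = sel.spec, sel.model
            for step in sel.trace:
                logger.info("selection: %s", step)
        else:
            design = build_design(cohort_s, grs_table, bmi_s, spec)
            stats = GroupStats.from_arrays(
                design.X, design.Z, design.y, design.group_labels,
                design.columns, design.re_names,
            )
            model = fit_from_stats(stats, config.estimation, spec=spec)
        logger.info(
            "fitted %s model: %d children, %d obs, loglik %.2f, converged=%s",
            config.sex, model.n_children, model.n_obs, model.loglik, model.converged,
        )
        written.append(bio.save_model(model, out / "model.json", stamp=stamp))

        # ------------------------------------------------ effects
        stage = "effects"
        rows = []
        for age in config.ages:
            e = marginal_grs_effect(model, age)
            rows.append(["grs", age, np.nan, 2.5, e.estimate, e.se, e.ci_low, e.ci_high, e.p_value])
            for g in config.grs_levels:
                for months in config.ebf_levels:
                    e = ebf_effect(model, age, months, g)
                    rows.append([config.exposure, age, g, months, e.estimate, e.se,
                                 e.ci_low, e.ci_high, e.p_value])
        for g in config.grs_levels:
            comp = grs_compensation(model, max(config.ages), g, max(config.ebf_levels))
            rows.append(["compensation_deciles", max(config.ages), g,
                         max(config.ebf_levels), comp.delta_deciles, np.nan, np.nan,
                         np.nan, np.nan])
        effects_df = pd.DataFrame(
            rows,
            columns=["effect", "age", "grs", "months", "estimate", "se", "ci_low",
                     "ci_high", "p"],
        )
        written.append(bio.write_table(effects_df, out / "effects.csv"))

        # ------------------------------------------------ adiposity
        stage = "adiposity"
        design = build_design(cohort_s, grs_table, bmi_s, spec)
        stats = GroupStats.from_arrays(
            design.X, design.Z, design.y, design.group_labels,
            design.columns, design.re_names,
        )
        ref = (config.grs_levels[0], 0.0)
        arows = []
        for g in config.grs_levels:
            for months in (0.0, *config.ebf_levels):
                ap = estimate_apar(model, g, months)
                shift = ap.age_at_ar - estimate_apar(model, *ref).age_at_ar
                ci_lo = ci_hi = np.nan
                if config.bootstrap_B > 0 and (g, months) != ref:
                    bres = cluster_bootstrap(
                        stats,
                        apar_shift_statistic(spec, (g, months), ref, "AR", theta0=model.theta),
                        B=config.bootstrap_B,
                        seed=config.stage_seed("bootstrap"),
                        label=f"AR shift ({g},{months}) vs {ref}",
                    )
                    ci_lo, ci_hi = bres.ci_low, bres.ci_high
                    logger.info(
                        "bootstrap %s: %d/%d failed", bres.statistic_label,
                        bres.n_failed, bres.B,
                    )
                arows.append([g, months, ap.age_at_ap, ap.bmi_at_ap, ap.age_at_ar,
                              ap.bmi_at_ar, shift, ci_lo, ci_hi])
        apar_df = pd.DataFrame(
            arows,
            columns=["grs", "ebf_months", "age_at_ap", "bmi_at_ap", "age_at_ar",
                     "bmi_at_ar", "ar_shift_vs_ref", "ci_low", "ci_high"],
        )
        written.append(bio.write_table(apar_df, out / "apar.csv"))

        manifest = {
            "stamp": stamp,
            "artifacts": sorted(p.name for p in written),
            "config": config.to_dict(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return {
            "cohort": cohort, "grs": grs_table, "bmi": bmi, "model": model,
            "effects": effects_df, "apar": apar_df, "out_dir": out,
        }
    except Exception as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("bmigrowth").removeHandler(handler)
        handler.close()
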