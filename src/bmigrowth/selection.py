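"""Knot and interaction-term selection for the trajectory model.

Knot triples are chosen by BIC over a finite candidate grid of ML fits;
interaction term groups are then pruned by backward elimination with
likelihood-ratio tests at alpha = 0.05, respecting the model hierarchy
(a lower-order group is only testable once every group containing it has
been removed). The final model is refit by REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import ModelSpec, build_design
from .lmm import FittedModel, fit_design
from .splines import SplineSpec

__all__ = ["SelectionResult", "select_model"]

logger = logging.getLogger(__name__)

#: droppable interaction-term groups, most complex first
_GROUP_ORDER = ("grs:exposure", "exposure", "grs")


@dataclass
class SelectionResult:
    spec: ModelSpec
    model: FittedModel
    trace: list = field(default_factory=list)


def _fit(cohort, grs, long, spec, estimation) -> FittedModel:
    return fit_design(build_design(cohort, grs, long, spec), estimation)


def _drop_group(spec: ModelSpec, group: str) -> ModelSpec:
    """Remove one interaction group (its spline interactions and, for the
    three-way group, the grs x exposure product main effect)."""
    inter = tuple(t for t in spec.interactions if t != group)
    return spec.replace(interactions=inter)


def _n_params(spec: ModelSpec) -> int:
    return len(spec.fixed_columns())


def select_model(
    cohort: pd.DataFrame,
    grs: pd.DataFrame,
    long: pd.DataFrame,
    candidate_knots,
    base_spec: ModelSpec | None = None,
    alpha: float = 0.05,
    prune_terms: bool = True,
) -> SelectionResult:
    """Choose spline knots by BIC and prune interaction groups by LRT.

    ``candidate_knots`` is an iterable of (K1, K2, K3) triples. All
    selection fits use ML (likelihoods are comparable across fixed-effect
    structures); the winning specification is refit by REML.
    """
    base_spec = base_spec or ModelSpec()
    candidate_knots = [tuple(float(v) for v in k) for k in candidate_knots]
    if not candidate_knots:
        raise ValueError("candidate_knots must be non-empty")
    trace: list = []

    best = None
    n_failed = 0
    for knots in candidate_knots:
        spec = base_spec.replace(spline=SplineSpec(knots=knots, age_domain=base_spec.spline.age_domain))
        try:
            m = _fit(cohort, grs, long, spec, "ml")
        except Exception as exc:  # noqa: BLE001 - candidate may be numerically hopeless
            n_failed += 1
            trace.append({"stage": "knots", "knots": knots, "error": str(exc)})
            continue
        bic = -2.0 * m.loglik + _n_params(spec) * np.log(m.n_obs)
        trace.append({"stage": "knots", "knots": knots, "bic": float(bic),
                      "converged": m.converged})
        if m.converged and (best is None or bic < best[0]):
            best = (bic, spec, m)
    if best is None:
        raise RuntimeError(
            f"no knot candidate converged ({n_failed} of {len(candidate_knots)} failed outright)"
        )
    _, spec, current = best
    logger.info("selected knots %s by BIC", spec.spline.knots)

    if prune_terms and len(candidate_knots) >= 1:
        improved = True
        while improved:
            improved = False
            droppable = [g for g in _GROUP_ORDER if _is_droppable(spec, g)]
            tests = []
            for g in droppable:
                red_spec = _drop_group(spec, g)
                red = _fit(cohort, grs, long, red_spec, "ml")
                lr = 2.0 * (current.loglik - red.loglik)
                df = _n_params(spec) - _n_params(red_spec)
                p = float(sps.chi2.sf(max(lr, 0.0), df))
                tests.append((p, g, red_spec, red))
                trace.append({"stage": "terms", "dropped": g, "lr": float(lr),
                              "df": df, "p": p})
            if tests:
                p, g, red_spec, red = max(tests, key=lambda t: t[0])
                if p > alpha:
                    logger.info("eliminating %s (LRT p=%.3g)", g, p)
                    spec, current = red_spec, red
                    improved = True

    final_spec = spec.replace(estimation="reml")
    final = _fit(cohort, grs, long, final_spec, "reml")
    trace.append({"stage": "final", "knots": final_spec.spline.knots,
                  "interactions": final_spec.interactions})
    return SelectionResult(spec=final_spec, model=final, trace=trace)


def _is_droppable(spec: ModelSpec, group: str) -> bool:
    if group not in spec.interactions:
        return False
    if group == "grs" and "grs:exposure" in spec.interactions:
        return False
    if group == "exposure" and "grs:exposure" in spec.interactions:
        return False
    return True
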