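import numpy as np
import pandas as pd
import pytest

from bmigrowth import default_truth, simulate_study
from bmigrowth.design import ModelSpec
from bmigrowth.lmm import GroupStats, fit_from_stats


@pytest.fixture(scope="session")
def default_spec():
    return ModelSpec(exposure="ebf", confounders=())


@pytest.fixture(scope="session")
def small_study():
    """One simulated 250-child single-sex cohort shared across tests."""
    truth = default_truth(n_children=250, seed=42, sex_ratio=1.0)
    return simulate_study(truth)


@pytest.fixture(scope="session")
def small_model(small_study):
    """REML fit of the default model on the shared small cohort."""
    from bmigrowth.design import build_design

    truth = small_study["truth"]
    d = build_design(small_study["cohort"], small_study["grs"], small_study["bmi"], truth.model_spec)
    stats = GroupStats.from_arrays(
        d.X, d.Z, d.y, d.group_labels, d.columns, d.re_names
    )
    return fit_from_stats(stats, "reml", spec=truth.model_spec)


def random_interaction_model(seed: int, spec: ModelSpec | None = None):
    """A synthetic fitted model with random coefficients and covariance,
    for exercising contrast algebra independently of any data fit."""
    from bmigrowth.lmm import FittedModel

    spec = spec or ModelSpec(exposure="ebf", confounders=())
    rng = np.random.default_rng(seed)
    cols = spec.fixed_columns()
    p = len(cols)
    coef = pd.Series(rng.normal(0.0, 0.5, p), index=cols)
    a = rng.normal(size=(p, p)) / np.sqrt(p)
    vcov = pd.DataFrame(a @ a.T * 0.01, index=cols, columns=cols)
    return FittedModel(
        coef=coef, vcov=vcov, re_cov=np.zeros((0, 0)), re_names=[],
        sigma2=1.0, loglik=0.0, method="reml", converged=True,
        n_children=0, n_obs=0, spec=spec,
    )
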