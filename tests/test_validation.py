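"""Fast checks of the Geweke harness building blocks (the full test is an
acceptance criterion and runs in test_acceptance.py)."""

import numpy as np
import pandas as pd

from jdmjm.mcmc import GibbsSampler, McmcConfig
from jdmjm.model import ModelData
from jdmjm.validation import (
    _draw_design,
    _draw_outcomes,
    _draw_prior_params,
    _statistics,
    geweke_design_cohort,
    tight_prior_config,
)


def test_design_cohort_layout():
    cohort, config = geweke_design_cohort(n_patients=30, seed=0)
    assert cohort.n_patients == 30
    assert len(cohort.df) == 60
    assert cohort.df["sym"].isna().sum() > 0
    assert config.covariate_names == ["sym", "trt"]


def test_prior_draws_respect_structure():
    cohort, config = geweke_design_cohort(seed=0)
    data = ModelData(cohort, config)
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = _draw_prior_params(rng, config, data.n_patients)
        p.validate()
        assert p.gamma[1] == 1  # treatment column always included
        np.linalg.cholesky(p.Sigma)


def test_simulated_outcomes_in_support():
    cohort, config = geweke_design_cohort(seed=1)
    data = ModelData(cohort, config)
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = _draw_prior_params(rng, config, data.n_patients)
        X = _draw_design(rng, p, data)
        y, ab = _draw_outcomes(rng, p, data, X, config)
        for k in (1, 2, 3):
            lo, hi = data.support[k]
            cont = y[k][~ab[k]]
            assert np.all((cont > lo) & (cont < hi))


def test_single_transition_invariance():
    """One Gibbs sweep applied to an exact joint sample must leave the
    monitored statistics prior-distributed (paired z-test, generous bound)."""
    cohort, config = geweke_design_cohort(seed=2)
    data = ModelData(cohort, config)
    rng = np.random.default_rng(2)
    mcmc = McmcConfig(n_chains=1, n_iterations=10, n_burnin=5, thin=5, seed=2,
                      adapt=False, n_re_updates=1)
    sampler = GibbsSampler(data, config, mcmc)
    before, after = [], []
    for _ in range(250):
        p = _draw_prior_params(rng, config, data.n_patients)
        X = _draw_design(rng, p, data)
        y, ab = _draw_outcomes(rng, p, data, X, config)
        sampler.set_outcome_data(y, ab)
        sampler.set_state(p, X)
        before.append(_statistics(sampler.get_params(), y))
        sampler.sweep(rng, adapt=False)
        after.append(_statistics(sampler.get_params(), y))
    d = pd.DataFrame(after) - pd.DataFrame(before)
    se = d.std(ddof=1) / np.sqrt(len(d))
    z = (d.mean() / se.replace(0.0, np.nan)).dropna()
    # ~30 statistics; a systematic error shows up as |z| far beyond 5
    assert np.abs(z.to_numpy()).max() < 5.0
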