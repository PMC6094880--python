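import math

import numpy as np

from jdmjm import (
    CohortDesign,
    ModelConfig,
    default_truth,
    filter_history_complete,
    preselect_covariates,
    simulate_cohort,
)


def test_keeps_top_half_plus_treatments(small_cohort):
    cohort, _, truth = small_cohort
    cohort, _ = filter_history_complete(cohort)
    res = preselect_covariates(cohort)
    candidates = [c.name for c in truth.roster
                  if c.role in ("sign_symptom", "history_baseline")]
    treatments = [c.name for c in truth.roster if c.role == "treatment"]
    kept_candidates = [n for n in res.selected if n in candidates]
    assert len(kept_candidates) == math.ceil(len(candidates) / 2)
    for t in treatments:
        assert t in res.selected
    # selected preserves roster order
    order = [c.name for c in truth.roster]
    assert res.selected == sorted(res.selected, key=order.index)


def test_strong_effect_outranks_null():
    truth = default_truth("selection_test")
    cohort, _ = simulate_cohort(CohortDesign(n_patients=80, seed=21), truth)
    res = preselect_covariates(cohort)
    # x01 carries effects on all four outcomes; x04..x09 are null
    nulls = [f"x{i:02d}" for i in range(4, 10)]
    assert res.ranking["x01"] > np.median([res.ranking[n] for n in nulls])
    assert "x01" in res.selected


def test_restrict_config_and_cohort(small_cohort):
    cohort, _, truth = small_cohort
    cohort, _ = filter_history_complete(cohort)
    config = ModelConfig(roster=truth.roster)
    res = preselect_covariates(cohort, config)
    rconfig = res.restrict(config)
    rcohort = res.restrict_cohort(cohort)
    assert rconfig.covariate_names == res.selected
    assert rcohort.covariate_names == res.selected
    assert set(rcohort.df.columns) >= set(res.selected)
    assert len(rcohort.df) == len(cohort.df)
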