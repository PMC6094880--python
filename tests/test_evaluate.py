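import numpy as np
import pytest

from jdmjm import (
    McmcConfig,
    brier_scores,
    leave_patients_out,
    posterior_predictive_bands,
    prob_abnormal_given_others_normal,
    random_intercept_correlations,
    scaled_brier,
)


def test_brier_scores_hand_values():
    pred = [1.0, 0.0, 0.5, 0.5]
    obs = [1, 0, 1, 0]
    brier, ref, scaled = brier_scores(pred, obs)
    assert brier == pytest.approx(0.125)
    assert ref == pytest.approx(0.25)
    assert scaled == pytest.approx(0.5)


def test_brier_degenerate_prevalence_returns_none():
    _, ref, scaled = brier_scores([0.2, 0.1], [0, 0])
    assert ref == 0.0
    assert scaled is None


def test_predictive_bands_structure(small_fit):
    cohort, config, draws = small_fit
    bands = posterior_predictive_bands(draws, cohort, config, seed=2)
    t = bands.table
    n_obs = sum(cohort.df[n].notna().sum() for n in
                ("ck", "cmas", "mmt8", "pga"))
    assert len(t) == n_obs
    assert ((t["pit"] >= 0) & (t["pit"] <= 1)).all()
    assert (t["lower"] <= t["upper"]).all()
    assert 0.0 <= bands.outside_fraction_pit <= 1.0
    # the raw count is conservative relative to the nominal rate by design
    assert bands.outside_fraction_raw <= bands.outside_fraction_pit + 0.05


def test_bands_deterministic_given_seed(small_fit):
    cohort, config, draws = small_fit
    b1 = posterior_predictive_bands(draws, cohort, config, seed=5)
    b2 = posterior_predictive_bands(draws, cohort, config, seed=5)
    assert b1.outside_fraction_pit == b2.outside_fraction_pit
    assert np.array_equal(b1.table["pit"], b2.table["pit"])


def test_scaled_brier_reports(small_fit):
    cohort, config, draws = small_fit
    reports = scaled_brier(draws, cohort, config)
    assert set(reports) == {"ck", "cmas", "mmt8", "pga"}
    for rep in reports.values():
        assert 0.0 <= rep.brier <= 1.0
        assert rep.n_visits > 0
        if rep.scaled is not None:
            # the model should beat the prevalence reference in sample
            assert rep.scaled > 0.0


def test_random_intercept_correlations(small_fit):
    _, _, draws = small_fit
    corrs = random_intercept_correlations(draws)
    assert len(corrs) == 6
    for c in corrs:
        lo, hi = c.ci95
        assert -1.0 <= lo <= c.rho_hat <= hi <= 1.0
    pairs = {c.pair for c in corrs}
    assert ("cmas", "mmt8") in pairs


def test_conditional_abnormality(small_fit):
    cohort, config, draws = small_fit
    res = prob_abnormal_given_others_normal(draws, cohort, config, "pga")
    if res.n_visits:
        assert 0.0 <= res.q1 <= res.median <= res.q3 <= 1.0
        assert len(res.per_visit) == res.n_visits
    with pytest.raises(KeyError):
        prob_abnormal_given_others_normal(draws, cohort, config, "esr")


def test_leave_patients_out_holds_out_requested(small_cohort, small_fit):
    cohort, config, _ = small_fit
    mcmc = McmcConfig(n_chains=1, n_iterations=200, n_burnin=100, thin=5,
                      seed=23)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = leave_patients_out(cohort, config, mcmc, k=3, seed=4)
    assert len(res.held_out_patients) == 3
    assert set(res.table["patient_id"]) == set(res.held_out_patients)
    assert 0.0 <= res.coverage_pit <= 1.0
    for name, agree in res.classification_agreement.items():
        assert 0.0 <= agree <= 1.0
        assert name in res.baseline_agreement


def test_leave_patients_out_k0_is_plain_fit(small_fit):
    cohort, config, _ = small_fit
    mcmc = McmcConfig(n_chains=1, n_iterations=60, n_burnin=30, thin=5, seed=2)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = leave_patients_out(cohort, config, mcmc, k=0)
    assert res.held_out_patients == []
    assert res.coverage_pit is None
    assert res.draws.n_draws == 6


def test_leave_patients_out_insufficient_patients(small_fit):
    cohort, config, _ = small_fit
    mcmc = McmcConfig(n_chains=1, n_iterations=60, n_burnin=30, thin=5, seed=2)
    with pytest.raises(ValueError, match="cannot hold out"):
        leave_patients_out(cohort, config, mcmc, k=10_000)
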