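import numpy as np
import pandas as pd
import pytest

from jdmjm import CohortDesign, SyntheticTruth, default_truth, simulate_cohort
from jdmjm.simulate import truncnorm_rvs


def test_simulation_is_deterministic():
    truth = default_truth("paper_like")
    design = CohortDesign(n_patients=20, seed=42)
    c1, l1 = simulate_cohort(design, truth)
    c2, l2 = simulate_cohort(design, truth)
    pd.testing.assert_frame_equal(c1.df, c2.df)
    assert np.array_equal(l1.b, l2.b)


def test_seed_changes_data():
    truth = default_truth("paper_like")
    c1, _ = simulate_cohort(CohortDesign(n_patients=20, seed=1), truth)
    c2, _ = simulate_cohort(CohortDesign(n_patients=20, seed=2), truth)
    assert not c1.df["ck"].equals(c2.df["ck"])


def test_visit_schedule_quarterly_then_annual():
    d = CohortDesign(n_patients=1, jitter_sd_days=0.0, seed=0)
    times = d.schedule(4.0)
    early = times[times <= 2.0]
    assert np.allclose(np.diff(early), 0.25)
    late = times[times > 2.0]
    assert np.allclose(np.diff(late), 1.0)


def test_hurdle_point_mass_present(small_cohort):
    cohort, latent, _ = small_cohort
    for name in ("cmas", "mmt8", "pga"):
        frac = latent.at_best[name].mean()
        assert 0.05 < frac < 0.7, f"{name} at-best fraction {frac}"


def test_outcomes_respect_bounds(small_cohort):
    cohort, _, _ = small_cohort
    df = cohort.df
    assert (df["ck"] > 0).all()
    assert df["cmas"].between(0, 52).all()
    assert df["mmt8"].between(0, 80).all()
    assert df["pga"].between(0, 10).all()


def test_missingness_rate_in_range(small_cohort):
    cohort, _, truth = small_cohort
    for j, cov in enumerate(truth.roster):
        rate = cohort.df[cov.name].isna().mean()
        assert abs(rate - truth.missing_rate[j]) < 0.05


def test_truth_json_round_trip(tmp_path):
    truth = default_truth("selection_test")
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = SyntheticTruth.from_json(path)
    assert np.allclose(back.beta, truth.beta)
    assert np.allclose(back.Sigma, truth.Sigma)
    assert [c.name for c in back.roster] == [c.name for c in truth.roster]


def test_truth_validation_rejects_bad_sigma():
    truth = default_truth("null")
    bad = np.eye(4)
    bad[0, 1] = bad[1, 0] = 2.0  # not positive definite
    with pytest.raises(ValueError, match="positive definite"):
        SyntheticTruth(
            roster=truth.roster, beta0=truth.beta0, beta_time=truth.beta_time,
            beta=truth.beta, gamma=truth.gamma, alpha=truth.alpha,
            Sigma=bad, tau_slope=truth.tau_slope,
            sigma_resid=truth.sigma_resid,
            covariate_prevalence=truth.covariate_prevalence,
            missing_rate=truth.missing_rate,
        )


def test_gamma_zero_forces_zero_beta():
    truth = default_truth("paper_like")
    beta = truth.beta.copy()
    j = int(np.nonzero(truth.gamma == 0)[0][0])
    beta[0, j] = 0.5
    with pytest.raises(ValueError, match="gamma"):
        SyntheticTruth(
            roster=truth.roster, beta0=truth.beta0, beta_time=truth.beta_time,
            beta=beta, gamma=truth.gamma, alpha=truth.alpha,
            Sigma=truth.Sigma, tau_slope=truth.tau_slope,
            sigma_resid=truth.sigma_resid,
            covariate_prevalence=truth.covariate_prevalence,
            missing_rate=truth.missing_rate,
        )


def test_truncnorm_draws_stay_in_support():
    rng = np.random.default_rng(0)
    mu = np.array([-50.0, -1.0, 0.5, 3.0, 50.0])
    for _ in range(200):
        z = truncnorm_rvs(mu, 0.7, 0.0, 2.0, rng.uniform(size=5))
        assert np.all((z > 0.0) & (z < 2.0))


def test_truncnorm_matches_scipy_distribution():
    from scipy import stats

    rng = np.random.default_rng(3)
    u = rng.uniform(size=20000)
    z = truncnorm_rvs(1.2, 0.8, 0.0, 3.0, u)
    ref = stats.truncnorm((0.0 - 1.2) / 0.8, (3.0 - 1.2) / 0.8,
                          loc=1.2, scale=0.8)
    ks = stats.kstest(z, ref.cdf)
    assert ks.pvalue > 0.01
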