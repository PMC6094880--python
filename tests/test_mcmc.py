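import math

import numpy as np
import pytest

import jdmjm._likelihood as lk
from jdmjm import McmcConfig, ModelData, fit, visit_loglik
from jdmjm.mcmc import GibbsSampler, _initialize


# ---------------------------------------------------------------------------
# Delta kernels against brute-force recomputation
# ---------------------------------------------------------------------------

def brute_normal(y, mu, sigma):
    return (-np.log(sigma) - 0.5 * np.log(2 * np.pi)
            - 0.5 * ((y - mu) / sigma) ** 2)


def brute_trunc(y, mu, sigma, lo, hi):
    from scipy import stats
    return stats.truncnorm.logpdf(y, (lo - mu) / sigma, (hi - mu) / sigma,
                                  loc=mu, scale=sigma)


def test_normal_delta_scalar_matches_brute_force(rng):
    y = rng.normal(5, 1, size=50)
    mu = rng.normal(5, 1, size=50)
    d = 0.37
    got = lk.normal_delta_scalar(y, mu, d, 0.8)
    want = np.sum(brute_normal(y, mu + d, 0.8) - brute_normal(y, mu, 0.8))
    assert got == pytest.approx(want, abs=1e-10)


def test_trunc_delta_kernels_match_brute_force(rng):
    lo, hi = 0.0, 7.2
    y = rng.uniform(1, 7, size=40)
    mu = rng.normal(5, 2, size=40)
    sig = 0.6
    lz = lk.log_trunc_z_vec(mu, sig, lo, hi)
    buf = np.empty(40)
    d = -0.45
    got = lk.trunc_delta_scalar(y, mu, d, sig, lo, hi, lz, buf)
    want = np.sum(brute_trunc(y, mu + d, sig, lo, hi)
                  - brute_trunc(y, mu, sig, lo, hi))
    assert got == pytest.approx(want, abs=1e-9)
    # per-row variant
    shift = rng.normal(0, 0.5, size=40)
    diff = np.empty(40)
    lk.trunc_delta_rows(y, mu, shift, sig, lo, hi, lz, buf, diff)
    want_rows = (brute_trunc(y, mu + shift, sig, lo, hi)
                 - brute_trunc(y, mu, sig, lo, hi))
    assert np.allclose(diff, want_rows, atol=1e-9)
    # sigma change
    got_s = lk.trunc_sigma_delta(y, mu, sig, 0.9, lo, hi, lz, buf)
    want_s = np.sum(brute_trunc(y, mu, 0.9, lo, hi)
                    - brute_trunc(y, mu, sig, lo, hi))
    assert got_s == pytest.approx(want_s, abs=1e-9)


def test_bern_delta_matches_brute_force(rng):
    eta = rng.normal(0, 2, size=60)
    ab = rng.uniform(size=60) < 0.4

    def ll(e):
        p = 1.0 / (1.0 + np.exp(-e))
        return np.sum(np.where(ab, np.log(p), np.log1p(-p)))

    d = 0.8
    assert lk.bern_delta_scalar(ab, eta, d) == pytest.approx(
        ll(eta + d) - ll(eta), abs=1e-9)
    shift = rng.normal(0, 1, size=60)
    assert lk.bern_delta_vec(ab, eta, shift) == pytest.approx(
        ll(eta + shift) - ll(eta), abs=1e-9)


def test_log_phi_interval_tails():
    from scipy import stats
    for a, b in [(-1.0, 2.0), (5.0, 9.0), (-9.0, -5.0), (20.0, 30.0)]:
        if a > 0:  # upper tail: difference of survival functions stays finite
            want = math.log(stats.norm.sf(a) - stats.norm.sf(b))
        else:
            want = math.log(stats.norm.cdf(b) - stats.norm.cdf(a))
        assert lk.log_phi_interval(a, b) == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# Sampler cache consistency and likelihood agreement
# ---------------------------------------------------------------------------

@pytest.fixture()
def sampler(small_cohort, small_config):
    cohort, _, _ = small_cohort
    data = ModelData(cohort, small_config)
    mcmc = McmcConfig(n_chains=1, n_iterations=60, n_burnin=30, thin=5, seed=9)
    s = GibbsSampler(data, small_config, mcmc)
    rng = np.random.default_rng(7)
    params, X0, dropped = _initialize(data, small_config, rng)
    assert not dropped
    s.set_state(params, X0)
    return s, rng


def test_caches_consistent_after_sweeps(sampler):
    s, rng = sampler
    for _ in range(30):
        s.sweep(rng, adapt=True)
    mu_c = [m.copy() for m in s.mu]
    lz_c = [None] + [z.copy() for z in s.lz[1:]]
    eta_c = [e.copy() for e in s.eta]
    Xk_c = [x.copy() for x in s._Xk]
    xsub_c = [[np.array(sub) for sub in row] for row in s._xsub]
    s.refresh_caches()
    for k in range(4):
        assert np.allclose(mu_c[k], s.mu[k], atol=1e-10)
        assert np.array_equal(Xk_c[k], s._Xk[k])
        for j in range(s.config.n_covariates):
            assert np.array_equal(xsub_c[k][j], s._xsub[k][j])
    for k in (1, 2, 3):
        ci = s.cont_idx[k]
        assert np.allclose(lz_c[k][ci], s.lz[k][ci], atol=1e-10)
    for h in range(3):
        assert np.allclose(eta_c[h], s.eta[h], atol=1e-10)


def test_full_loglik_matches_visit_oracle(sampler, small_cohort, small_config):
    s, _ = sampler
    cohort, _, _ = small_cohort
    total = 0.0
    for row, v in enumerate(cohort.iter_visits()):
        total += visit_loglik(s.p, v, small_config, x_override=s.X[row])
    assert s.full_loglik() == pytest.approx(total, abs=1e-8)


def test_conjugate_ck_update_keeps_mu_exact(sampler):
    s, rng = sampler
    s._update_beta_ck(rng)
    mu_cached = s.mu[0].copy()
    s.refresh_caches()
    assert np.allclose(mu_cached, s.mu[0], atol=1e-12)


def test_missing_cells_stay_binary(sampler):
    s, rng = sampler
    for _ in range(10):
        s.sweep(rng)
    vals = s.missing_values()
    assert set(np.unique(vals)) <= {0.0, 1.0}
    # observed cells were never touched
    d = s.data
    assert np.array_equal(s.X[~d.miss_mask],
                          np.nan_to_num(d.X_obs, nan=0.0)[~d.miss_mask])


def test_gamma_zero_zeroes_beta(sampler):
    s, rng = sampler
    for _ in range(20):
        s.sweep(rng)
    p = s.p
    off = np.nonzero(p.gamma == 0)[0]
    assert np.all(p.beta[:, off] == 0.0)


# ---------------------------------------------------------------------------
# fit()
# ---------------------------------------------------------------------------

def test_fit_is_deterministic(small_cohort, small_config):
    cohort, _, _ = small_cohort
    mcmc = McmcConfig(n_chains=2, n_iterations=40, n_burnin=20, thin=5, seed=3)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d1 = fit(cohort, small_config, mcmc)
        d2 = fit(cohort, small_config, mcmc)
    for name in ("beta0", "beta", "Sigma", "b", "x_miss", "sigma_resid"):
        assert np.array_equal(d1.stacked(name), d2.stacked(name)), name


def test_fit_shapes_and_diagnostics(small_cohort, small_config):
    cohort, _, truth = small_cohort
    mcmc = McmcConfig(n_chains=2, n_iterations=40, n_burnin=20, thin=5, seed=3)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(cohort, small_config, mcmc)
    P = len(truth.roster)
    assert draws.stacked("beta").shape == (8, 4, P)
    assert draws.stacked("Sigma").shape == (8, 4, 4)
    assert set(draws.inclusion_probabilities()) == {c.name for c in truth.roster}
    assert {"parameter", "rhat", "ess", "flagged"} <= set(draws.diagnostics.columns)
    # treatments are never deselected
    pips = draws.inclusion_probabilities()
    for c in truth.roster:
        if c.role == "treatment":
            assert pips[c.name] == 1.0


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_chains=1, n_iterations=100, n_burnin=50, thin=7, seed=0)
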