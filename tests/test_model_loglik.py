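import math

import numpy as np
import pytest
from scipy import stats

from jdmjm import (
    Covariate,
    ModelConfig,
    VisitRecord,
    default_outcome_specs,
    hurdle_probability,
    linear_predictor,
    marginal_loglik_patient,
    visit_loglik,
)
from jdmjm.outcomes import OUTCOME_NAMES, transform_outcome

from conftest import make_params


def scipy_visit_oracle(params, visit, config):
    """Independent density summation with scipy distributions."""
    specs = config.outcome_specs
    total = 0.0
    x = np.array([visit.covariates[n] for n in config.covariate_names])
    for name, value in visit.outcomes.items():
        k = OUTCOME_NAMES.index(name)
        spec = specs[name]
        mu = (params.beta0[k] + params.beta_time[k] * visit.time_years
              + (params.gamma * params.beta[k]) @ x
              + params.b[visit.patient_index, k])
        if name == "ck":
            mu += params.s[visit.patient_index] * visit.time_years
            total += stats.norm.logpdf(math.log(value), mu,
                                       params.sigma_resid[k])
            continue
        h = ["cmas", "mmt8", "pga"].index(name)
        eta = (params.alpha[h, 0] + params.alpha[h, 1] * visit.time_years
               + params.alpha[h, 2] * params.b[visit.patient_index, k])
        pi = stats.logistic.cdf(eta)
        if spec.is_best(value):
            total += math.log(pi)
        else:
            lo, hi = spec.continuous_support()
            sig = params.sigma_resid[k]
            a, b = (lo - mu) / sig, (hi - mu) / sig
            total += math.log1p(-pi) + stats.truncnorm.logpdf(
                transform_outcome(spec, value), a, b, loc=mu, scale=sig)
    return total


@pytest.fixture()
def two_patient_fixture(roster3, rng):
    config = ModelConfig(roster=roster3)
    params = make_params(config, n_patients=2, rng=rng)
    visits = [
        VisitRecord("p0", 0, 0.0, {"ck": 420.0, "cmas": 31.0, "mmt8": 64.0,
                                   "pga": 4.5},
                    {"sym_a": 1.0, "hist_b": 0.0, "trt_c": 1.0}),
        VisitRecord("p0", 0, 0.75, {"ck": 130.0, "cmas": 52.0, "mmt8": 80.0,
                                    "pga": 0.0},
                    {"sym_a": 0.0, "hist_b": 0.0, "trt_c": 1.0}),
        VisitRecord("p1", 1, 0.25, {"ck": 95.0, "cmas": 47.5, "pga": 1.0},
                    {"sym_a": 1.0, "hist_b": 1.0, "trt_c": 0.0}),
    ]
    return config, params, visits


def test_visit_loglik_matches_scipy_oracle(two_patient_fixture):
    config, params, visits = two_patient_fixture
    for v in visits:
        ours = visit_loglik(params, v, config)
        oracle = scipy_visit_oracle(params, v, config)
        assert ours == pytest.approx(oracle, abs=1e-10)


def test_linear_predictor_components(two_patient_fixture):
    config, params, visits = two_patient_fixture
    v = visits[0]
    x = np.array([1.0, 0.0, 1.0])
    mu = linear_predictor(params, v, "cmas", config)
    expect = (params.beta0[1] + (params.gamma * params.beta[1]) @ x
              + params.b[0, 1])
    assert mu == pytest.approx(expect)
    # CK picks up the random slope
    v2 = visits[1]
    mu_ck = linear_predictor(params, v2, "ck", config)
    assert mu_ck == pytest.approx(
        params.beta0[0] + params.beta_time[0] * 0.75
        + (params.gamma * params.beta[0]) @ np.array([0.0, 0.0, 1.0])
        + params.b[0, 0] + params.s[0] * 0.75)


def test_hurdle_probability_logistic(two_patient_fixture):
    config, params, visits = two_patient_fixture
    v = visits[0]
    pi = hurdle_probability(params, v, "pga", config)
    eta = (params.alpha[2, 0] + params.alpha[2, 1] * v.time_years
           + params.alpha[2, 2] * params.b[0, 3])
    assert pi == pytest.approx(1.0 / (1.0 + math.exp(-eta)))


def test_missing_covariate_requires_override(two_patient_fixture):
    config, params, _ = two_patient_fixture
    v = VisitRecord("p0", 0, 0.0, {"ck": 100.0},
                    {"sym_a": float("nan"), "hist_b": 0.0, "trt_c": 1.0})
    with pytest.raises(ValueError, match="missing covariates"):
        visit_loglik(params, v, config)
    ok = visit_loglik(params, v, config,
                      x_override=np.array([1.0, 0.0, 1.0]))
    assert math.isfinite(ok)


def test_marginal_matches_conjugate_closed_form(two_patient_fixture):
    """CK-only visits: integrating the random intercept (and slope) over the
    Gaussian prior has the closed form y ~ MVN(mu, sigma^2 I + S00 J + tau t t')."""
    config, params, _ = two_patient_fixture
    times = [0.0, 0.5, 1.25]
    cks = [300.0, 180.0, 140.0]
    visits = [VisitRecord("p0", 0, t, {"ck": c},
                          {"sym_a": 1.0, "hist_b": 0.0, "trt_c": 1.0})
              for t, c in zip(times, cks)]
    x = np.array([1.0, 0.0, 1.0])
    t = np.array(times)
    y = np.log(cks)
    mu = (params.beta0[0] + params.beta_time[0] * t
          + (params.gamma * params.beta[0]) @ x)
    s2 = params.sigma_resid[0] ** 2

    # intercept only
    cov = s2 * np.eye(3) + params.Sigma[0, 0]
    expect = stats.multivariate_normal.logpdf(y, mean=mu, cov=cov)
    got = marginal_loglik_patient(params, visits, config, dims=(0,),
                                  include_slope=False)
    assert not got.warned
    assert got.value == pytest.approx(expect, abs=1e-6)

    # intercept + random time slope
    cov_s = cov + params.tau_slope * np.outer(t, t)
    expect_s = stats.multivariate_normal.logpdf(y, mean=mu, cov=cov_s)
    got_s = marginal_loglik_patient(params, visits, config, dims=(0,),
                                    include_slope=True)
    assert got_s.value == pytest.approx(expect_s, abs=1e-6)


def test_marginal_quadrature_refinement_flag(two_patient_fixture):
    config, params, _ = two_patient_fixture
    visits = [VisitRecord("p0", 0, 0.0, {"ck": 200.0},
                          {"sym_a": 0.0, "hist_b": 0.0, "trt_c": 0.0})]
    res = marginal_loglik_patient(params, visits, config, dims=(0,))
    assert res.refinement_delta < 1e-8
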