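import numpy as np
import pytest

from jdmjm import (
    CohortDesign,
    Covariate,
    JointModelParams,
    McmcConfig,
    ModelConfig,
    default_truth,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient paper-like cohort shared across tests (read-only)."""
    truth = default_truth("paper_like")
    cohort, latent = simulate_cohort(CohortDesign(n_patients=40, seed=11), truth)
    return cohort, latent, truth


@pytest.fixture(scope="session")
def small_config(small_cohort):
    _, _, truth = small_cohort
    return ModelConfig(roster=truth.roster)


@pytest.fixture()
def tiny_mcmc():
    return McmcConfig(n_chains=1, n_iterations=60, n_burnin=30, thin=5,
                      seed=5, adapt=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_params(config: ModelConfig, n_patients: int,
                rng: np.random.Generator) -> JointModelParams:
    """A valid, moderately dispersed parameter state for likelihood tests."""
    P = config.n_covariates
    gamma = np.ones(P, int)
    A = rng.normal(size=(4, 4)) * 0.2
    Sigma = A @ A.T + 0.3 * np.eye(4)
    return JointModelParams(
        beta0=np.array([5.0, 5.8, 8.0, 1.4]) + 0.1 * rng.normal(size=4),
        beta_time=0.1 * rng.normal(size=4),
        beta=0.3 * rng.normal(size=(4, P)),
        alpha=0.5 * rng.normal(size=(3, 3)),
        gamma=gamma,
        b=rng.multivariate_normal(np.zeros(4), Sigma, size=n_patients),
        s=0.15 * rng.normal(size=n_patients),
        Sigma=Sigma,
        tau_slope=0.0225,
        sigma_resid=np.array([0.8, 0.6, 0.5, 0.5]),
        theta_miss=np.full(P, 0.4),
    )


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A short (not converged) fit on the shared cohort, for evaluation APIs."""
    import warnings

    from jdmjm import fit

    cohort, _, truth = small_cohort
    config = ModelConfig(roster=truth.roster)
    mcmc = McmcConfig(n_chains=1, n_iterations=400, n_burnin=200, thin=5,
                      seed=17)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(cohort, config, mcmc)
    return cohort, config, draws


@pytest.fixture()
def roster3():
    return [Covariate("sym_a", "sign_symptom"),
            Covariate("hist_b", "history_baseline"),
            Covariate("trt_c", "treatment")]
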