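"""The joint hurdle model: parameters, priors, likelihood and pre-selection.

Model structure
---------------
For patient *i*, visit *j*, the four outcomes on their analysis scales are

* log CK_ij  ~ Normal(mu_ij0, sigma_0) with
  mu_ij0 = beta0_0 + betat_0 t_ij + sum_p gamma_p beta_0p x_ijp + b_i0 + s_i t_ij
* sqrt CMAS / sqrt MMT8 / sqrt PGA follow a hurdle: with probability
  pi_ijk = logit^-1(alpha0_k + alphat_k t_ij + alphab_k b_ik) the outcome sits
  exactly at its best clinical value; otherwise it is Normal(mu_ijk, sigma_k)
  truncated to the continuous support (so point mass and continuous branch are
  disjoint).

The subject random intercepts (b_i0..b_i3) are jointly multivariate normal
with covariance Sigma estimated from the data; the CK random time slope s_i is
an independent Normal(0, tau).  A single inclusion indicator gamma_p switches
covariate *p* on or off for all four outcomes simultaneously (spike-and-slab
with an exact zero spike).  Missing covariate cells are modelled as
Bernoulli(theta_p) and imputed inside the sampler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _likelihood as lk
from .cohort import Cohort, Covariate, VisitRecord
from .outcomes import (
    HURDLE_NAMES,
    OUTCOME_INDEX,
    OUTCOME_NAMES,
    OutcomeSpec,
    default_outcome_specs,
    transform_outcome,
)

__all__ = [
    "PriorSpec",
    "ModelConfig",
    "JointModelParams",
    "ModelData",
    "linear_predictor",
    "visit_loglik",
    "marginal_loglik_patient",
    "preselect_covariates",
    "PreselectionResult",
]


# ---------------------------------------------------------------------------
# Priors and configuration
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Hyperparameters of the (configurable) prior.

    Defaults: slab SD 2 on the transformed scales, inclusion probability 1/2,
    inverse-Wishart(df=6, I) on Sigma, half-Normal(2) residual SDs,
    Normal(0, 2^2) hurdle coefficients, inverse-Gamma(3, 0.2) slope variance,
    Beta(1, 1) missingness rates.
    """

    beta_slab_sd: float = 2.0
    inclusion_prior_prob: float = 0.5
    intercept_prior_mean: np.ndarray = field(
        default_factory=lambda: np.zeros(4))
    intercept_prior_sd: float = 10.0
    time_prior_sd: float = 2.0
    sigma_resid_halfnormal_scale: float = 2.0
    alpha_prior_sd: float = 2.0
    sigma_prior_df: float = 6.0
    sigma_prior_scale: float = 1.0          # scale matrix = this * I4
    tau_prior_shape: float = 3.0
    tau_prior_scale: float = 0.2
    miss_prior_a: float = 1.0
    miss_prior_b: float = 1.0

    def __post_init__(self) -> None:
        self.intercept_prior_mean = np.asarray(self.intercept_prior_mean, float)
        pos = [self.beta_slab_sd, self.intercept_prior_sd, self.time_prior_sd,
               self.sigma_resid_halfnormal_scale, self.alpha_prior_sd,
               self.sigma_prior_scale, self.tau_prior_shape,
               self.tau_prior_scale, self.miss_prior_a, self.miss_prior_b]
        if any(v <= 0 for v in pos):
            raise ValueError("all prior hyperparameters must be positive")
        if not 0.0 < self.inclusion_prior_prob < 1.0:
            raise ValueError("inclusion_prior_prob must lie in (0, 1)")
        if self.sigma_prior_df <= 5.0:  # dimension 4 + 1
            raise ValueError("inverse-Wishart df must exceed dimension + 1")


@dataclass
class ModelConfig:
    """Covariate roster, outcome specs, priors and structural switches."""

    roster: list[Covariate]
    outcome_specs: dict[str, OutcomeSpec] = field(default_factory=default_outcome_specs)
    priors: PriorSpec = field(default_factory=PriorSpec)
    #: roles whose covariates are subject to Bayesian variable selection;
    #: treatments are always forced into the model.
    selectable_roles: tuple[str, ...] = ("sign_symptom", "history_baseline")
    #: whether the hurdle probability loads on the outcome's random intercept.
    hurdle_random_intercept_loading: bool = True
    #: whether missing covariate cells are imputed inside the sampler.
    impute_missing: bool = True

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.roster]

    @property
    def n_covariates(self) -> int:
        return len(self.roster)

    @property
    def selectable(self) -> np.ndarray:
        """Boolean mask over the roster: True where gamma may switch."""
        return np.array([c.role in self.selectable_roles for c in self.roster])

    def describe(self) -> str:
        """Human-readable resolved specification for audit."""
        lines = ["joint hurdle model of (ck, cmas, mmt8, pga)"]
        for name in OUTCOME_NAMES:
            s = self.outcome_specs[name]
            hur = (f"hurdle at {s.best_value}" if s.has_hurdle else "no hurdle")
            lines.append(
                f"  {name}: {s.transform} scale, {hur}, inactive when value "
                f"{'<=' if s.cutoff_direction == 'le' else '>='} {s.remission_cutoff}"
            )
        for c in self.roster:
            sel = "selectable" if c.role in self.selectable_roles else "forced"
            lines.append(f"  covariate {c.name} [{c.role}, {sel}]")
        p = self.priors
        lines.append(
            f"  priors: slab sd {p.beta_slab_sd}, inclusion prob "
            f"{p.inclusion_prior_prob}, Sigma ~ IW({p.sigma_prior_df}, "
            f"{p.sigma_prior_scale} I), sigma_resid ~ halfN({p.sigma_resid_halfnormal_scale}), "
            f"alpha ~ N(0, {p.alpha_prior_sd}^2), tau ~ IG({p.tau_prior_shape}, "
            f"{p.tau_prior_scale}), theta ~ Beta({p.miss_prior_a}, {p.miss_prior_b})"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class JointModelParams:
    """One full parameter state of the joint model.

    Shapes: ``beta0``/``beta_time``/``sigma_resid`` (4,), ``beta`` (4, P),
    ``alpha`` (3, 3) rows cmas/mmt8/pga and columns (intercept, time, random-
    intercept loading), ``gamma`` (P,), ``b`` (N, 4), ``s`` (N,), ``Sigma``
    (4, 4), ``theta_miss`` (P,).
    """

    beta0: np.ndarray
    beta_time: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    b: np.ndarray
    s: np.ndarray
    Sigma: np.ndarray
    tau_slope: float
    sigma_resid: np.ndarray
    theta_miss: np.ndarray

    def copy(self) -> "JointModelParams":
        return JointModelParams(
            beta0=self.beta0.copy(), beta_time=self.beta_time.copy(),
            beta=self.beta.copy(), alpha=self.alpha.copy(),
            gamma=self.gamma.copy(), b=self.b.copy(), s=self.s.copy(),
            Sigma=self.Sigma.copy(), tau_slope=float(self.tau_slope),
            sigma_resid=self.sigma_resid.copy(),
            theta_miss=self.theta_miss.copy(),
        )

    def validate(self) -> None:
        if np.linalg.eigvalsh(self.Sigma).min() <= 0:
            raise ValueError("Sigma must be positive definite")
        if np.any(self.sigma_resid <= 0):
            raise ValueError("sigma_resid must be positive")
        if self.tau_slope < 0:
            raise ValueError("tau_slope must be >= 0")
        bad = (self.gamma == 0) & np.any(self.beta != 0.0, axis=0)
        if np.any(bad):
            raise ValueError("gamma == 0 requires zero beta column (all outcomes)")


# ---------------------------------------------------------------------------
# Likelihood (single-visit API)
# ---------------------------------------------------------------------------

def _covariate_vector(config: ModelConfig, visit: VisitRecord,
                      x_override: np.ndarray | None) -> np.ndarray:
    if x_override is not None:
        return np.asarray(x_override, float)
    x = np.array([visit.covariates[n] for n in config.covariate_names], float)
    if np.any(np.isnan(x)):
        raise ValueError(
            "visit has missing covariates; supply x_override with imputed values"
        )
    return x


def linear_predictor(
    params: JointModelParams,
    visit: VisitRecord,
    outcome: str,
    config: ModelConfig,
    x_override: np.ndarray | None = None,
    b_override: np.ndarray | None = None,
    s_override: float | None = None,
) -> float:
    """Transformed-scale mean of one outcome at one visit.

    intercept + time effect + sum_p gamma_p beta_kp x_p + b_ik, plus the
    subject time slope for CK.  Random effects default to the rows of
    ``params.b``/``params.s`` for the visit's patient.
    """
    if outcome not in OUTCOME_INDEX:
        raise KeyError(f"unknown outcome {outcome!r}")
    k = OUTCOME_INDEX[outcome]
    x = _covariate_vector(config, visit, x_override)
    b = params.b[visit.patient_index] if b_override is None else np.asarray(b_override, float)
    s = float(params.s[visit.patient_index]) if s_override is None else float(s_override)
    mu = (params.beta0[k] + params.beta_time[k] * visit.time_years
          + float((params.gamma * params.beta[k]) @ x) + b[k])
    if outcome == "ck":
        mu += s * visit.time_years
    return float(mu)


def hurdle_probability(
    params: JointModelParams, visit: VisitRecord, outcome: str,
    config: ModelConfig, b_override: np.ndarray | None = None,
) -> float:
    """Probability that a hurdle outcome sits at its best clinical value."""
    h = list(HURDLE_NAMES).index(outcome)
    k = OUTCOME_INDEX[outcome]
    b = params.b[visit.patient_index] if b_override is None else np.asarray(b_override, float)
    a0, a_t, a_b = params.alpha[h]
    load = a_b * b[k] if config.hurdle_random_intercept_loading else 0.0
    eta = a0 + a_t * visit.time_years + load
    return float(1.0 / (1.0 + math.exp(-eta)))


def visit_loglik(
    params: JointModelParams,
    visit: VisitRecord,
    config: ModelConfig,
    x_override: np.ndarray | None = None,
    b_override: np.ndarray | None = None,
    s_override: float | None = None,
) -> float:
    """Joint log-likelihood of one visit's observed outcomes.

    Missing outcomes contribute nothing.  CK contributes a Gaussian term on
    the log scale; hurdle outcomes contribute log(pi) at the best value and
    log(1 - pi) plus a truncated-Gaussian term otherwise.
    """
    total = 0.0
    for name, value in visit.outcomes.items():
        spec = config.outcome_specs[name]
        if not spec.in_bounds(value) or (name == "ck" and value <= 0):
            raise ValueError(f"{name}={value} outside outcome bounds")
        k = OUTCOME_INDEX[name]
        mu = linear_predictor(params, visit, name, config,
                              x_override, b_override, s_override)
        sigma = float(params.sigma_resid[k])
        y = transform_outcome(spec, value)
        if not spec.has_hurdle:
            total += lk.normal_ll_sum(np.array([y]), np.array([mu]), sigma)
            continue
        pi = hurdle_probability(params, visit, name, config, b_override)
        if spec.is_best(value):
            total += math.log(pi) if pi > 0 else -math.inf
        else:
            lo, hi = spec.continuous_support()
            total += (math.log1p(-pi) if pi < 1 else -math.inf)
            total += lk.trunc_ll_sum(np.array([y]), np.array([mu]), sigma, lo, hi)
    return float(total)


# ---------------------------------------------------------------------------
# Marginal likelihood by deterministic quadrature (oracle for the sampler)
# ---------------------------------------------------------------------------

@dataclass
class QuadratureResult:
    value: float
    refinement_delta: float
    warned: bool


def _marginal_gh(params, visits, config, dims, n_nodes, include_slope):
    from numpy.polynomial.hermite import hermgauss
    from scipy.linalg import cholesky

    nodes, weights = hermgauss(n_nodes)
    dims = list(dims)
    d = len(dims) + (1 if include_slope else 0)
    Sig = params.Sigma[np.ix_(dims, dims)]
    L = cholesky(Sig, lower=True)
    grids = np.meshgrid(*([nodes] * d), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=0)          # (d, n^d)
    W = np.ones(Z.shape[1])
    wg = np.meshgrid(*([weights] * d), indexing="ij")
    for g in wg:
        W = W * g.ravel()
    logW = np.log(W) - d * 0.5 * math.log(math.pi)
    n_int = len(dims)
    B = math.sqrt(2.0) * (L @ Z[:n_int])                       # (n_int, n^d)
    if include_slope:
        S = math.sqrt(2.0) * math.sqrt(params.tau_slope) * Z[n_int]
    lls = np.zeros(Z.shape[1])
    for q in range(Z.shape[1]):
        b = np.zeros(4)
        b[dims] = B[:, q]
        s = float(S[q]) if include_slope else 0.0
        lls[q] = sum(
            visit_loglik(params, v, config, b_override=b, s_override=s)
            for v in visits
        )
    m = np.max(lls + logW)
    return float(m + math.log(np.sum(np.exp(lls + logW - m))))


def marginal_loglik_patient(
    params: JointModelParams,
    visits: Sequence[VisitRecord],
    config: ModelConfig,
    dims: Sequence[int] = (0, 1, 2, 3),
    n_nodes: int = 20,
    include_slope: bool = False,
    refine_tol: float = 1e-4,
) -> QuadratureResult:
    """log of the random-effect-integrated likelihood of one patient.

    Deterministic Gauss-Hermite tensor quadrature over the requested random-
    intercept dimensions (and optionally the CK slope); dimensions not listed
    are fixed at zero.  Intended as a slow, independent oracle for sampler
    validation on patients with few visits.  The result is recomputed on a
    refined grid; a discrepancy above ``refine_tol`` sets ``warned``.
    """
    v1 = _marginal_gh(params, visits, config, dims, n_nodes, include_slope)
    v2 = _marginal_gh(params, visits, config, dims, n_nodes + 8, include_slope)
    delta = abs(v2 - v1)
    warned = delta > refine_tol
    if warned:
        warnings.warn(
            f"quadrature refinement changed the result by {delta:.2e}; "
            "increase n_nodes", stacklevel=2,
        )
    return QuadratureResult(value=v2, refinement_delta=delta, warned=warned)


# ---------------------------------------------------------------------------
# Univariate pre-selection
# ---------------------------------------------------------------------------

@dataclass
class PreselectionResult:
    """Outcome of the 50% univariate screen.

    ``selected`` lists the retained covariate names in roster order: the top
    half of candidates by evidence, plus every treatment covariate (always
    kept regardless of univariate performance).  ``ranking`` maps candidate
    name -> best absolute Wald statistic across the four outcomes.
    """

    selected: list[str]
    ranking: dict[str, float]
    failures: list[str]

    def restrict(self, config: ModelConfig) -> ModelConfig:
        roster = [c for c in config.roster if c.name in self.selected]
        return replace(config, roster=roster)

    def restrict_cohort(self, cohort: Cohort) -> Cohort:
        """Drop the screened-out covariate columns from the cohort."""
        from .cohort import build_cohort

        dropped = [c.name for c in cohort.covariates
                   if c.name not in self.selected]
        kept = [c for c in cohort.covariates if c.name in self.selected]
        df = cohort.df.drop(columns=dropped + ["patient_index"])
        return build_cohort(df, kept, cohort.outcome_specs)


def preselect_covariates(
    cohort: Cohort,
    config: ModelConfig | None = None,
    candidate_roles: tuple[str, ...] = ("sign_symptom", "history_baseline"),
) -> PreselectionResult:
    """Screen candidate covariates with univariate linear mixed models.

    For each candidate covariate and each outcome, fit
    ``transformed outcome ~ covariate + time`` with a patient random
    intercept; rank candidates by their largest absolute Wald statistic across
    the four outcomes and keep the top half (ceiling).  Treatment covariates
    are always retained.  Non-convergent fits rank the covariate last.
    """
    import statsmodels.api as sm

    candidates = [c.name for c in cohort.covariates if c.role in candidate_roles]
    treatments = cohort.names_with_role("treatment")
    if len(candidates) < 1:
        return PreselectionResult(selected=list(treatments), ranking={}, failures=[])

    df = cohort.df
    ranking: dict[str, float] = {}
    failures: list[str] = []
    for name in candidates:
        best = 0.0
        ok = False
        for out_name in OUTCOME_NAMES:
            spec = cohort.outcome_specs[out_name]
            sub = df[[out_name, name, "time_years", "patient_index"]].dropna()
            if sub[name].nunique() < 2 or len(sub) < 10:
                continue
            y = transform_outcome(spec, sub[out_name].to_numpy())
            exog = np.column_stack([
                np.ones(len(sub)), sub[name].to_numpy(), sub["time_years"].to_numpy()
            ])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MixedLM(
                        y, exog, groups=sub["patient_index"].to_numpy()
                    ).fit(reml=True, method="lbfgs")
                tval = float(np.abs(fit.tvalues[1]))
                if math.isfinite(tval):
                    best = max(best, tval)
                    ok = True
            except Exception:
                continue
        if not ok:
            failures.append(name)
            best = -math.inf
        ranking[name] = best

    n_keep = math.ceil(len(candidates) / 2)
    # ties and failures resolved by roster order (stable sort on -statistic)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-ranking[candidates[i]], i))
    kept = {candidates[i] for i in order[:n_keep]}
    selected = [c.name for c in cohort.covariates
                if c.name in kept or c.role == "treatment"]
    return PreselectionResult(selected=selected, ranking=ranking, failures=failures)


# ---------------------------------------------------------------------------
# Prepared arrays for the sampler
# ---------------------------------------------------------------------------

class ModelData:
    """Cohort unpacked into flat arrays for the Gibbs sampler.

    One block per outcome: global visit indices where the outcome is observed,
    transformed values, hurdle indicator, time and patient index restricted to
    those visits, and a global-row -> in-block position map for the imputation
    step.
    """

    def __init__(self, cohort: Cohort, config: ModelConfig):
        df = cohort.df
        names = config.covariate_names
        if set(names) != {c.name for c in cohort.covariates}:
            raise ValueError("config roster does not match cohort covariates")
        hist = [c.name for c in config.roster if c.role == "history_baseline"]
        if hist and df[hist].isna().any().any():
            raise ValueError(
                "history covariates contain missing values; run "
                "filter_history_complete first"
            )
        self.config = config
        self.n_visits = len(df)
        self.n_patients = int(df["patient_index"].nunique())
        self.pid = df["patient_index"].to_numpy(int)
        self.t = df["time_years"].to_numpy(float)
        self.X_obs = df[names].to_numpy(float)            # NaN where missing
        self.miss_mask = np.isnan(self.X_obs)
        self.imputable = np.array(
            [c.role != "history_baseline" for c in config.roster])
        if np.any(self.miss_mask[:, ~self.imputable]):
            raise ValueError("missing values in non-imputable covariates")

        self.idx: list[np.ndarray] = []
        self.y: list[np.ndarray] = []
        self.at_best: list[np.ndarray] = []
        self.t_k: list[np.ndarray] = []
        self.pid_k: list[np.ndarray] = []
        self.pos_in_k = np.full((4, self.n_visits), -1, dtype=int)
        self.support: list[tuple[float, float]] = []
        for k, name in enumerate(OUTCOME_NAMES):
            spec = config.outcome_specs[name]
            vals = df[name].to_numpy(float)
            obs = np.isfinite(vals)
            idx = np.nonzero(obs)[0]
            yk = transform_outcome(spec, vals[idx]) if len(idx) else np.empty(0)
            yk = np.asarray(yk, float)
            if spec.has_hurdle:
                ab = np.isclose(vals[idx], spec.best_value, rtol=0, atol=1e-9)
            else:
                ab = np.zeros(len(idx), bool)
            self.idx.append(idx)
            self.y.append(yk)
            self.at_best.append(ab)
            self.t_k.append(self.t[idx])
            self.pid_k.append(self.pid[idx])
            self.pos_in_k[k, idx] = np.arange(len(idx))
            self.support.append(spec.continuous_support())

        # visits-per-patient (for conjugate bookkeeping)
        self.visits_per_patient = np.bincount(self.pid, minlength=self.n_patients)
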