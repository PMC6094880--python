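"""Model assessment: credible bands, scaled Brier scores, leave-patients-out
prediction, random-intercept correlations and conditional abnormality.

All assessments work from posterior draws.  In-sample checks condition on each
patient's sampled random effects (the draws of b and s); held-out prediction
integrates the random effects over their population distribution by sampling
fresh effects per posterior draw.

Because the hurdle outcomes carry a point mass at the best clinical value, a
plain count of observations outside central mixture-quantile intervals is
structurally conservative (the atom can absorb an entire tail).  The band
report therefore carries both that raw count and a randomized-PIT outside
fraction, which is uniform-calibrated even in the presence of atoms and is
the quantity that converges to 1 - level under a correctly specified model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .simulate import truncnorm_rvs

from .cohort import Cohort, build_cohort
from .model import ModelConfig, ModelData
from .mcmc import McmcConfig, PosteriorDraws, fit
from .outcomes import HURDLE_NAMES, OUTCOME_NAMES, transform_outcome

__all__ = [
    "posterior_predictive_bands", "scaled_brier", "brier_scores",
    "leave_patients_out", "random_intercept_correlations",
    "prob_abnormal_given_others_normal",
    "BrierReport", "CorrelationSummary", "PredictiveBands", "LocoResult",
    "ConditionalAbnormality",
]

_HURDLE_K = (1, 2, 3)


# ---------------------------------------------------------------------------
# Per-draw predictors
# ---------------------------------------------------------------------------

def _design_per_draw(draws: PosteriorDraws, data: ModelData):
    """Imputed design matrix per draw: (n_draws, n_visits, P) built lazily.

    Returns a function draw_index -> X matrix (a shared base with the missing
    cells overwritten).
    """
    base = np.nan_to_num(data.X_obs, nan=0.0)
    cells = draws.miss_cells
    xm = draws.stacked("x_miss")

    def X_for(d: int) -> np.ndarray:
        X = base.copy()
        for c, (r, j) in enumerate(cells):
            X[r, j] = xm[d, c]
        return X

    return X_for


def _design_imputed(draws: PosteriorDraws, data: ModelData,
                    rng: np.random.Generator):
    """Design per draw for *new* data: missing cells drawn from the posterior
    covariate prevalences, Bernoulli(theta_j) per draw."""
    base = np.nan_to_num(data.X_obs, nan=0.0)
    rows, cols = np.nonzero(data.miss_mask)
    theta = draws.stacked("theta_miss")
    fills = rng.uniform(size=(draws.n_draws, len(rows)))

    def X_for(d: int) -> np.ndarray:
        X = base.copy()
        if len(rows):
            X[rows, cols] = (fills[d] < theta[d, cols]).astype(float)
        return X

    return X_for


def _predictors(draws: PosteriorDraws, data: ModelData, config: ModelConfig,
                b_mode: str = "posterior", rng: np.random.Generator | None = None):
    """Per-draw linear predictors and hurdle logits.

    Returns (mus, etas, sigmas, alphas): mus[k] and etas[h] have shape
    (n_draws, n_obs_k).  ``b_mode`` is ``"posterior"`` (use the stored random
    effects and imputed design of each draw; in-sample) or ``"prior"`` (new
    patients: random effects sampled from MVN(0, Sigma_draw) and missing
    covariate cells from Bernoulli(theta_draw)).
    """
    nd = draws.n_draws
    beta0 = draws.stacked("beta0")
    beta_time = draws.stacked("beta_time")
    beta = draws.stacked("beta")
    alpha = draws.stacked("alpha")
    Sig = draws.stacked("Sigma")
    tau = draws.stacked("tau_slope")
    sigmas = draws.stacked("sigma_resid")
    if b_mode == "posterior":
        X_for = _design_per_draw(draws, data)
        b_all = draws.stacked("b")
        s_all = draws.stacked("s")
    else:
        if rng is None:
            raise ValueError("prior-integrated prediction needs an rng")
        X_for = _design_imputed(draws, data, rng)
        N = data.n_patients
        b_all = np.empty((nd, N, 4))
        s_all = np.empty((nd, N))
        for d in range(nd):
            L = np.linalg.cholesky(Sig[d])
            b_all[d] = rng.normal(size=(N, 4)) @ L.T
            s_all[d] = rng.normal(0.0, math.sqrt(max(tau[d], 0.0)), size=N)
    mus = [np.empty((nd, len(data.idx[k]))) for k in range(4)]
    etas = [np.empty((nd, len(data.idx[k]))) for k in _HURDLE_K]
    loading = config.hurdle_random_intercept_loading
    for d in range(nd):
        X = X_for(d)
        for k in range(4):
            idx = data.idx[k]
            mu = (beta0[d, k] + beta_time[d, k] * data.t_k[k]
                  + X[idx] @ beta[d, k] + b_all[d][data.pid_k[k], k])
            if k == 0:
                mu = mu + s_all[d][data.pid_k[0]] * data.t_k[0]
            mus[k][d] = mu
        for h, k in enumerate(_HURDLE_K):
            eta = alpha[d, h, 0] + alpha[d, h, 1] * data.t_k[k]
            if loading:
                eta = eta + alpha[d, h, 2] * b_all[d][data.pid_k[k], k]
            etas[h][d] = eta
    return mus, etas, sigmas, alpha


def _sample_y_rep(data: ModelData, config: ModelConfig, mus, etas, sigmas,
                  rng: np.random.Generator):
    """Posterior-predictive replicates on the transformed scale.

    Returns a list of (n_draws, n_obs_k) arrays; hurdle atoms are represented
    by the transformed best value.
    """
    reps = []
    nd = mus[0].shape[0]
    for k in range(4):
        n_k = mus[k].shape[1]
        if k == 0:
            reps.append(mus[0] + sigmas[:, [0]] * rng.normal(size=(nd, n_k)))
            continue
        h = k - 1
        spec = config.outcome_specs[OUTCOME_NAMES[k]]
        lo, hi = data.support[k]
        sig = sigmas[:, [k]]
        z = truncnorm_rvs(mus[k], sig, lo, hi, rng.uniform(size=(nd, n_k)))
        pi = 1.0 / (1.0 + np.exp(-etas[h]))
        at_best = rng.uniform(size=(nd, n_k)) < pi
        z[at_best] = spec.transformed_best
        reps.append(z)
    return reps


# ---------------------------------------------------------------------------
# Credible bands
# ---------------------------------------------------------------------------

@dataclass
class PredictiveBands:
    table: pd.DataFrame                 # per visit/outcome: observed, lo, hi, pit
    outside_fraction_raw: float         # plain count outside [lo, hi]
    outside_fraction_pit: float         # randomized-PIT count, atom-aware
    level: float


def posterior_predictive_bands(
    draws: PosteriorDraws,
    cohort: Cohort,
    config: ModelConfig,
    level: float = 0.95,
    seed: int = 0,
    b_mode: str = "posterior",
) -> PredictiveBands:
    """Central posterior-predictive intervals per visit and outcome.

    Intervals are mixture quantiles on the transformed scale (the hurdle atom
    included), computed from sampled predictive replicates.  ``pit`` is the
    randomized probability integral transform of the observation within its
    replicate set; an observation counts as PIT-outside when its PIT falls in
    either alpha/2 tail.

    ``b_mode="posterior"`` conditions on each patient's posterior random
    effects (the per-patient band reported by the pipeline); because those
    effects are informed by the same observations, the in-sample PIT is
    conservative.  ``b_mode="prior"`` integrates random effects over their
    population distribution per draw, the construction under which observed
    data drawn from the model have a uniform PIT — use it for calibration
    checks against simulated cohorts.
    """
    data = ModelData(cohort, config)
    rng = np.random.default_rng(seed)
    mus, etas, sigmas, _ = _predictors(draws, data, config, b_mode, rng=rng)
    reps = _sample_y_rep(data, config, mus, etas, sigmas, rng)
    a = (1.0 - level) / 2.0
    rows = []
    n_out_raw = n_out_pit = n_tot = 0
    for k, name in enumerate(OUTCOME_NAMES):
        idx = data.idx[k]
        if len(idx) == 0:
            continue
        lo = np.quantile(reps[k], a, axis=0)
        hi = np.quantile(reps[k], 1.0 - a, axis=0)
        y = data.y[k]
        nd = reps[k].shape[0]
        less = (reps[k] < y[None, :] - 1e-12).sum(axis=0)
        eq = (np.abs(reps[k] - y[None, :]) <= 1e-12).sum(axis=0)
        v = rng.uniform(size=len(y))
        pit = (less + v * (eq + 1)) / (nd + 1)
        out_raw = (y < lo) | (y > hi)
        out_pit = (pit < a) | (pit > 1.0 - a)
        n_out_raw += int(out_raw.sum())
        n_out_pit += int(out_pit.sum())
        n_tot += len(y)
        rows.append(pd.DataFrame({
            "outcome": name,
            "patient_index": data.pid_k[k],
            "time_years": data.t_k[k],
            "observed_transformed": y,
            "lower": lo, "upper": hi, "pit": pit,
            "outside_raw": out_raw, "outside_pit": out_pit,
        }))
    table = pd.concat(rows, ignore_index=True)
    return PredictiveBands(
        table=table,
        outside_fraction_raw=n_out_raw / n_tot,
        outside_fraction_pit=n_out_pit / n_tot,
        level=level,
    )


# ---------------------------------------------------------------------------
# Scaled Brier score
# ---------------------------------------------------------------------------

@dataclass
class BrierReport:
    outcome: str
    brier: float
    reference_brier: float
    scaled: float | None                # None when prevalence is degenerate
    prevalence_inactive: float
    n_visits: int


def brier_scores(pred: np.ndarray, obs: np.ndarray):
    """(brier, reference, scaled) for probability predictions of a 0/1 event.

    The reference predicts the observed event prevalence for every visit;
    ``scaled = 1 - brier / reference`` (undefined when every observation is
    the same class).
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    brier = float(np.mean((pred - obs) ** 2))
    prev = float(np.mean(obs))
    ref = float(np.mean((prev - obs) ** 2))
    scaled = None if ref == 0.0 else 1.0 - brier / ref
    return brier, ref, scaled


def _p_inactive_per_draw(data: ModelData, config: ModelConfig, mus, etas,
                         sigmas) -> list[np.ndarray]:
    """P(outcome meets its remission cutoff) per draw and visit, analytic."""
    out = []
    for k, name in enumerate(OUTCOME_NAMES):
        spec = config.outcome_specs[name]
        cut = transform_outcome(spec, spec.remission_cutoff) \
            if spec.remission_cutoff > 0 else math.sqrt(spec.remission_cutoff)
        sig = sigmas[:, [k]]
        if not spec.has_hurdle:  # CK: P(log CK <= log cutoff)
            out.append(ndtr((cut - mus[k]) / sig))
            continue
        h = k - 1
        lo, hi = data.support[k]
        a = ndtr((lo - mus[k]) / sig)
        b = ndtr((hi - mus[k]) / sig)
        c = ndtr((cut - mus[k]) / sig)
        width = np.maximum(b - a, 1e-300)
        pi = 1.0 / (1.0 + np.exp(-etas[h]))
        if spec.cutoff_direction == "ge":   # CMAS, MMT8: best value counts
            p_cont = np.clip((b - c) / width, 0.0, 1.0)
        else:                               # PGA: atmass at 0 counts
            p_cont = np.clip((c - a) / width, 0.0, 1.0)
        out.append(pi + (1.0 - pi) * p_cont)
    return out


def scaled_brier(draws: PosteriorDraws, cohort: Cohort,
                 config: ModelConfig) -> dict[str, BrierReport]:
    """Scaled Brier score of cutoff classification, one report per outcome.

    Predicted inactive-probabilities are posterior means of the analytic
    per-draw probabilities conditional on each patient's random effects; the
    reference model predicts the observed prevalence of the inactive state.
    """
    data = ModelData(cohort, config)
    mus, etas, sigmas, _ = _predictors(draws, data, config, "posterior")
    p_inact = _p_inactive_per_draw(data, config, mus, etas, sigmas)
    reports = {}
    for k, name in enumerate(OUTCOME_NAMES):
        spec = config.outcome_specs[name]
        idx = data.idx[k]
        raw = cohort.df[name].to_numpy(float)[idx]
        obs = np.array([1.0 if spec.is_inactive(v) else 0.0 for v in raw])
        pred = p_inact[k].mean(axis=0)
        brier, ref, scaled = brier_scores(pred, obs)
        reports[name] = BrierReport(
            outcome=name, brier=brier, reference_brier=ref, scaled=scaled,
            prevalence_inactive=float(obs.mean()), n_visits=len(obs),
        )
    return reports


# ---------------------------------------------------------------------------
# Random-intercept correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    pair: tuple[str, str]
    rho_hat: float                       # posterior median
    ci95: tuple[float, float]


def random_intercept_correlations(draws: PosteriorDraws) -> list[CorrelationSummary]:
    """Posterior median and central 95% CI of the 6 intercept correlations."""
    Sig = draws.stacked("Sigma")
    sd = np.sqrt(np.einsum("dkk->dk", Sig))
    out = []
    for a in range(4):
        for b in range(a + 1, 4):
            rho = Sig[:, a, b] / (sd[:, a] * sd[:, b])
            lo, med, hi = np.percentile(rho, [2.5, 50.0, 97.5])
            out.append(CorrelationSummary(
                pair=(OUTCOME_NAMES[a], OUTCOME_NAMES[b]),
                rho_hat=float(med), ci95=(float(lo), float(hi)),
            ))
    return out


# ---------------------------------------------------------------------------
# Conditional abnormality
# ---------------------------------------------------------------------------

@dataclass
class ConditionalAbnormality:
    outcome: str
    per_visit: pd.DataFrame              # patient, time, p_abnormal
    median: float | None
    q1: float | None
    q3: float | None
    n_visits: int


def prob_abnormal_given_others_normal(
    draws: PosteriorDraws,
    cohort: Cohort,
    config: ModelConfig,
    target: str,
) -> ConditionalAbnormality:
    """Posterior-predictive abnormality probability of one outcome at visits
    where the other three outcomes are observed and inactive by their cutoffs.

    The probability conditions on the patient's posterior random effects;
    the summary is the median and quartiles (linear interpolation) across the
    qualifying visits.  An empty qualifying set yields a reported-empty result.
    """
    if target not in OUTCOME_NAMES:
        raise KeyError(f"unknown outcome {target!r}")
    data = ModelData(cohort, config)
    df = cohort.df
    others = [n for n in OUTCOME_NAMES if n != target]
    ok = np.ones(len(df), bool)
    for n in others:
        spec = config.outcome_specs[n]
        vals = df[n].to_numpy(float)
        obs = np.isfinite(vals)
        inact = np.zeros(len(df), bool)
        inact[obs] = [spec.is_inactive(v) for v in vals[obs]]
        ok &= obs & inact
    rows = np.nonzero(ok)[0]
    k = OUTCOME_NAMES.index(target)
    # restrict to rows where the target has a defined predictor (always true)
    mus, etas, sigmas, _ = _predictors(draws, data, config, "posterior")
    p_inact = _p_inactive_per_draw(data, config, mus, etas, sigmas)
    pos = data.pos_in_k[k, rows]
    keep = pos >= 0
    pos = pos[keep]
    rows = rows[keep]
    if len(rows) == 0:
        return ConditionalAbnormality(target, pd.DataFrame(), None, None, None, 0)
    p_abn = 1.0 - p_inact[k][:, pos].mean(axis=0)
    q1, med, q3 = np.percentile(p_abn, [25.0, 50.0, 75.0])
    table = pd.DataFrame({
        "patient_index": df["patient_index"].to_numpy()[rows],
        "time_years": df["time_years"].to_numpy()[rows],
        "p_abnormal": p_abn,
    })
    return ConditionalAbnormality(
        outcome=target, per_visit=table, median=float(med),
        q1=float(q1), q3=float(q3), n_visits=len(rows),
    )


# ---------------------------------------------------------------------------
# Leave-patients-out prediction
# ---------------------------------------------------------------------------

@dataclass
class LocoResult:
    held_out_patients: list[str]
    table: pd.DataFrame                  # per held-out visit/outcome
    coverage_pit: float | None           # PIT-based coverage of level bands
    classification_agreement: dict[str, float]
    baseline_agreement: dict[str, float]
    draws: PosteriorDraws


def leave_patients_out(
    cohort: Cohort,
    config: ModelConfig,
    mcmc: McmcConfig,
    k: int = 5,
    seed: int = 0,
    level: float = 0.95,
) -> LocoResult:
    """Refit without ``k`` randomly chosen patients and predict their
    trajectories with random effects integrated over the population
    distribution; their missing covariate cells are imputed per posterior
    draw from the covariate prevalences.

    ``k = 0`` performs the full fit unchanged (a determinism control).
    """
    if k == 0:
        draws = fit(cohort, config, mcmc)
        return LocoResult([], pd.DataFrame(), None, {}, {}, draws)
    if cohort.n_patients <= k:
        raise ValueError(
            f"cohort has only {cohort.n_patients} patients, cannot hold out {k}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(cohort.n_patients, size=k, replace=False).tolist())
    ids = cohort.patient_ids
    chosen_ids = [ids[i] for i in chosen]
    train_df = cohort.df[~cohort.df["patient_index"].isin(chosen)].drop(
        columns=["patient_index"])
    test_df = cohort.df[cohort.df["patient_index"].isin(chosen)].drop(
        columns=["patient_index"])
    train = build_cohort(train_df, cohort.covariates, cohort.outcome_specs)
    test = build_cohort(test_df, cohort.covariates, cohort.outcome_specs)
    draws = fit(train, config, mcmc)

    data = ModelData(test, config)
    mus, etas, sigmas, _ = _predictors(draws, data, config, "prior", rng)
    reps = _sample_y_rep(data, config, mus, etas, sigmas, rng)
    p_inact = _p_inactive_per_draw(data, config, mus, etas, sigmas)
    a = (1.0 - level) / 2.0
    rows = []
    n_in = n_tot = 0
    agree: dict[str, float] = {}
    base: dict[str, float] = {}
    for kk, name in enumerate(OUTCOME_NAMES):
        idx = data.idx[kk]
        if len(idx) == 0:
            continue
        spec = config.outcome_specs[name]
        y = data.y[kk]
        nd = reps[kk].shape[0]
        lo = np.quantile(reps[kk], a, axis=0)
        hi = np.quantile(reps[kk], 1.0 - a, axis=0)
        less = (reps[kk] < y[None, :] - 1e-12).sum(axis=0)
        eq = (np.abs(reps[kk] - y[None, :]) <= 1e-12).sum(axis=0)
        pit = (less + rng.uniform(size=len(y)) * (eq + 1)) / (nd + 1)
        inside = (pit >= a) & (pit <= 1.0 - a)
        n_in += int(inside.sum())
        n_tot += len(y)
        raw = test.df[name].to_numpy(float)[idx]
        obs = np.array([spec.is_inactive(v) for v in raw])
        pred = p_inact[kk].mean(axis=0)
        agree[name] = float(np.mean((pred > 0.5) == obs))
        # constant-prediction baseline: training prevalence of inactive state
        traw = train.df[name].to_numpy(float)
        tobs = np.array([spec.is_inactive(v) for v in traw[np.isfinite(traw)]])
        prev = float(tobs.mean())
        base[name] = float(np.mean((prev > 0.5) == obs))
        rows.append(pd.DataFrame({
            "outcome": name,
            "patient_id": [test.patient_ids[p] for p in
                           test.df["patient_index"].to_numpy()[idx]],
            "time_years": data.t_k[kk],
            "observed_transformed": y,
            "pred_median": np.quantile(reps[kk], 0.5, axis=0),
            "lower": lo, "upper": hi, "pit": pit,
            "p_inactive": pred, "observed_inactive": obs,
        }))
    return LocoResult(
        held_out_patients=chosen_ids,
        table=pd.concat(rows, ignore_index=True),
        coverage_pit=n_in / n_tot if n_tot else None,
        classification_agreement=agree,
        baseline_agreement=base,
        draws=draws,
    )
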