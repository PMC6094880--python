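"""Posterior sampling for the joint hurdle model.

A Metropolis-within-Gibbs sweep updates, in a fixed order:

1. missing covariate cells from their exact Bernoulli full conditionals;
2. the covariate rates theta by Beta conjugacy;
3. the CK regression coefficients by a conjugate multivariate Gaussian draw
   (the CK branch is plain Gaussian given the random effects) and the hurdle
   outcomes' coefficients by per-coordinate random-walk Metropolis (their
   continuous branch is truncated, hence non-conjugate);
4. the shared inclusion indicators gamma by Metropolised add/delete moves
   with slab proposals drawn from the prior (so the slab prior cancels and no
   marginal likelihood of the non-conjugate branches is needed);
5. the hurdle coefficients alpha by random-walk Metropolis;
6. the per-patient random effects (4 intercepts + CK slope) by joint
   5-dimensional random-walk proposals, one accept/reject per patient;
7. Sigma from its inverse-Wishart full conditional;
8. tau (slope variance) from its inverse-Gamma full conditional and the
   residual SDs by random-walk Metropolis on the log scale.

Proposal scales adapt towards standard acceptance targets during burn-in only
and are frozen afterwards, keeping the post-burn-in chain Markovian.  All
randomness flows from one integer seed through `numpy.random.SeedSequence`,
so runs are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import invwishart

from . import _likelihood as lk
from .cohort import Cohort
from .model import JointModelParams, ModelConfig, ModelData
from .outcomes import HURDLE_NAMES, OUTCOME_NAMES

__all__ = ["McmcConfig", "PosteriorDraws", "fit", "initialize",
           "convergence_report", "GibbsSampler"]

_HURDLE_K = (1, 2, 3)   # outcome indices of cmas, mmt8, pga


@dataclass
class McmcConfig:
    """Chain schedule and tuning knobs."""

    n_chains: int = 4
    n_iterations: int = 5000
    n_burnin: int = 2500
    thin: int = 5
    seed: int = 0
    n_re_updates: int = 2          # random-effect sweeps per iteration
    adapt: bool = True
    adapt_window: int = 50
    rhat_threshold: float = 1.05
    ess_threshold: float = 100.0
    init_scale_beta: float = 0.05
    init_scale_alpha: float = 0.15
    init_scale_b: float = 0.35
    init_scale_logsigma: float = 0.06

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iterations - self.n_burnin) % self.thin != 0:
            raise ValueError("(n_iterations - n_burnin) must be divisible by thin")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _initialize(data: ModelData, config: ModelConfig, rng: np.random.Generator):
    """Least-squares starting values; returns (params, X_init, dropped)."""
    P = config.n_covariates
    n = data.n_visits
    prev = np.empty(P)
    X0 = data.X_obs.copy()
    for j in range(P):
        col = data.X_obs[:, j]
        obs = ~np.isnan(col)
        prev[j] = col[obs].mean() if obs.any() else 0.5
        miss = ~obs
        if miss.any():
            X0[miss, j] = (rng.uniform(size=miss.sum()) < prev[j]).astype(float)

    dropped: list[str] = []
    for j, name in enumerate(config.covariate_names):
        col = data.X_obs[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0 or np.all(obs == obs[0]):
            dropped.append(name)
    if dropped:
        warnings.warn(f"constant covariates dropped from the model: {dropped}",
                      stacklevel=2)

    beta0 = np.zeros(4)
    beta_time = np.zeros(4)
    beta = np.zeros((4, P))
    sigma = np.ones(4)
    gamma = np.ones(P, int)
    gamma[[config.covariate_names.index(d) for d in dropped]] = 0

    for k in range(4):
        idx = data.idx[k]
        if len(idx) == 0:
            continue
        keep = ~data.at_best[k]
        rows = idx[keep]
        complete = ~np.isnan(data.X_obs[rows]).any(axis=1)
        rows = rows[complete]
        yk = data.y[k][keep][complete]
        if len(rows) < P + 3:
            rows = idx[keep]
            yk = data.y[k][keep]
            D = np.column_stack([np.ones(len(rows)), data.t[rows]])
            coef, *_ = np.linalg.lstsq(D, yk, rcond=None)
            beta0[k], beta_time[k] = coef
            resid = yk - D @ coef
        else:
            D = np.column_stack([np.ones(len(rows)), data.t[rows],
                                 X0[rows][:, gamma == 1]])
            coef, *_ = np.linalg.lstsq(D, yk, rcond=None)
            beta0[k], beta_time[k] = coef[0], coef[1]
            beta[k, gamma == 1] = coef[2:]
            resid = yk - D @ coef
        sigma[k] = max(float(np.std(resid)), 0.05)

    alpha = np.zeros((3, 3))
    for h, k in enumerate(_HURDLE_K):
        frac = float(np.mean(data.at_best[k])) if len(data.at_best[k]) else 0.1
        frac = min(max(frac, 0.02), 0.98)
        alpha[h, 0] = math.log(frac / (1.0 - frac))

    params = JointModelParams(
        beta0=beta0, beta_time=beta_time, beta=beta, alpha=alpha,
        gamma=gamma, b=np.zeros((data.n_patients, 4)),
        s=np.zeros(data.n_patients), Sigma=np.eye(4), tau_slope=0.04,
        sigma_resid=sigma,
        theta_miss=np.clip(prev, 0.02, 0.98),
    )
    return params, X0, dropped


def initialize(cohort: Cohort, config: ModelConfig, seed: int) -> JointModelParams:
    """Deterministic starting state (least squares on complete cases)."""
    data = ModelData(cohort, config)
    rng = np.random.default_rng(seed)
    params, _, _ = _initialize(data, config, rng)
    return params


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class GibbsSampler:
    """One-chain Metropolis-within-Gibbs machine over prepared ModelData.

    Holds the current parameter state, the imputed design matrix and cached
    linear predictors / hurdle logits per outcome; each update keeps the
    caches consistent.  `sweep` performs one full scan.
    """

    def __init__(self, data: ModelData, config: ModelConfig, mcmc: McmcConfig):
        self.data = data
        self.config = config
        self.mcmc = mcmc
        pri = config.priors
        P = config.n_covariates
        self.sel_cols = np.nonzero(config.selectable)[0]
        self.miss_cols = [j for j in range(P) if data.miss_mask[:, j].any()]
        self.miss_rows = {j: np.nonzero(data.miss_mask[:, j])[0]
                          for j in self.miss_cols}
        # flat list of (row, col) missing cells in a fixed order, for recording
        self.miss_cells = [(int(r), int(j)) for j in self.miss_cols
                           for r in self.miss_rows[j]]
        # proposal scales
        self.sc_beta = np.full((3, P + 2), mcmc.init_scale_beta)
        self.sc_alpha = np.full((3, 3), mcmc.init_scale_alpha)
        self.sc_b = np.full(data.n_patients, mcmc.init_scale_b)
        self.sc_lsig = np.full(4, mcmc.init_scale_logsigma)
        self._reset_counters()
        # priors unpacked
        self.prior_prec_int = 1.0 / pri.intercept_prior_sd ** 2
        self.prior_prec_time = 1.0 / pri.time_prior_sd ** 2
        self.prior_prec_slab = 1.0 / pri.beta_slab_sd ** 2
        self.log_odds_inc = math.log(pri.inclusion_prior_prob
                                     / (1.0 - pri.inclusion_prior_prob))
        self.p: JointModelParams | None = None
        self.X: np.ndarray | None = None
        # reusable scratch buffers (sized per outcome block)
        self._lzbuf = [np.empty(len(data.idx[k])) for k in range(4)]
        self._dbuf = [np.empty(len(data.idx[k])) for k in range(4)]

    # -- state management ---------------------------------------------------

    def set_state(self, params: JointModelParams, X: np.ndarray) -> None:
        self.p = params.copy()
        self.X = np.asarray(X, float).copy()
        self.refresh_caches()

    def refresh_caches(self) -> None:
        p, d = self.p, self.data
        self.mu = []
        for k in range(4):
            eff = p.gamma * p.beta[k]
            mu = (p.beta0[k] + p.beta_time[k] * d.t_k[k]
                  + self.X[d.idx[k]] @ eff + p.b[d.pid_k[k], k])
            if k == 0:
                mu = mu + p.s[d.pid_k[k]] * d.t_k[k]
            self.mu.append(mu)
        self.eta = []
        for h, k in enumerate(_HURDLE_K):
            eta = p.alpha[h, 0] + p.alpha[h, 1] * d.t_k[k]
            if self.config.hurdle_random_intercept_loading:
                eta = eta + p.alpha[h, 2] * p.b[d.pid_k[k], k]
            else:
                eta = eta + np.zeros(len(d.t_k[k]))
            self.eta.append(eta)
        # continuous-branch row indices and cached per-row log normalising
        # constants of the truncated Gaussians (entries at at-best rows unused)
        self.cont_idx: list = [None]
        self.lz: list = [None]
        self.y_c: list = [None]
        for k in _HURDLE_K:
            ci = np.nonzero(~d.at_best[k])[0]
            self.cont_idx.append(ci)
            self.y_c.append(d.y[k][ci])
            lzk = np.zeros(len(d.idx[k]))
            if len(ci):
                lo, hi = d.support[k]
                lzk[ci] = lk.log_trunc_z_vec(self.mu[k][ci],
                                             p.sigma_resid[k], lo, hi)
            self.lz.append(lzk)
        # static per-(missing column, outcome) index plan for the imputation
        # step: rows of the column's missing cells where outcome k is observed
        # (and, for hurdle outcomes, on the continuous branch)
        self._miss_plan = {}
        for j in self.miss_cols:
            rows = self.miss_rows[j]
            plan = []
            for k in range(4):
                pos = d.pos_in_k[k, rows]
                m = pos >= 0
                if k > 0:
                    m = m & ~_safe_at_best(d.at_best[k], pos)
                plan.append((np.nonzero(m)[0], pos[m]))
            self._miss_plan[j] = plan
        self._precompute_subsets()

    def _precompute_subsets(self, cols=None) -> None:
        """Cached gathered design blocks and, per covariate, the likelihood-
        relevant rows (x = 1; continuous branch for hurdles).

        With ``cols`` given, refreshes only those columns' row subsets (the
        imputation step keeps ``_Xk`` itself up to date incrementally).
        """
        d = self.data
        P = self.config.n_covariates
        if cols is None:
            self._Xk = [np.ascontiguousarray(self.X[d.idx[k]])
                        for k in range(4)]
            self._xsub = [[None] * P for _ in range(4)]
            cols = range(P)
        for k in range(4):
            Xk = self._Xk[k]
            for j in cols:
                m = Xk[:, j] != 0.0
                if k > 0:
                    m[d.at_best[k]] = False
                self._xsub[k][j] = np.nonzero(m)[0]

    def set_outcome_data(self, y: list[np.ndarray],
                         at_best: list[np.ndarray]) -> None:
        """Swap in new outcome observations (used by prior-data validation)."""
        for k in range(4):
            if len(y[k]) != len(self.data.y[k]):
                raise ValueError("replacement data must match observation count")
            self.data.y[k] = np.asarray(y[k], float)
            self.data.at_best[k] = np.asarray(at_best[k], bool)
        if self.p is not None:
            self.refresh_caches()

    def get_params(self) -> JointModelParams:
        return self.p.copy()

    # -- diagnostics --------------------------------------------------------

    def full_loglik(self) -> float:
        p, d = self.p, self.data
        total = lk.normal_ll_sum(d.y[0], self.mu[0], p.sigma_resid[0])
        for h, k in enumerate(_HURDLE_K):
            ab = d.at_best[k]
            total += lk.bern_ll_sum(ab, self.eta[h])
            cont = ~ab
            lo, hi = d.support[k]
            total += lk.trunc_ll_sum(d.y[k][cont], self.mu[k][cont],
                                     p.sigma_resid[k], lo, hi)
        return float(total)

    def _abort_if_nonfinite(self) -> None:
        if math.isfinite(self.full_loglik()):
            return
        p, d = self.p, self.data
        for k in range(4):
            vec = lk.normal_ll_vec(d.y[k], self.mu[k], p.sigma_resid[k]) \
                if k == 0 else lk.trunc_ll_vec(
                    d.y[k], self.mu[k], p.sigma_resid[k], *d.support[k])
            bad = np.nonzero(~np.isfinite(vec))[0]
            if len(bad):
                row = d.idx[k][bad[0]]
                raise RuntimeError(
                    f"non-finite log-likelihood at initialization: outcome "
                    f"{OUTCOME_NAMES[k]}, patient {d.pid[row]}, visit row {row}"
                )
        raise RuntimeError("non-finite log-likelihood at initialization")

    # -- adaptation ---------------------------------------------------------

    def _reset_counters(self) -> None:
        self.acc_beta = np.zeros((3, self.config.n_covariates + 2))
        self.try_beta = np.zeros_like(self.acc_beta)
        self.acc_alpha = np.zeros((3, 3))
        self.try_alpha = np.zeros_like(self.acc_alpha)
        self.acc_b = np.zeros(self.data.n_patients)
        self.try_b = np.zeros(self.data.n_patients)
        self.acc_lsig = np.zeros(4)
        self.try_lsig = np.zeros(4)

    def _adapt_scales(self) -> None:
        def tune(scale, acc, tries, target):
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(tries > 0, acc / np.maximum(tries, 1), target)
            return np.clip(scale * np.exp(rate - target), 1e-4, 10.0)

        self.sc_beta = tune(self.sc_beta, self.acc_beta, self.try_beta, 0.44)
        self.sc_alpha = tune(self.sc_alpha, self.acc_alpha, self.try_alpha, 0.44)
        self.sc_lsig = tune(self.sc_lsig, self.acc_lsig, self.try_lsig, 0.44)
        self.sc_b = tune(self.sc_b, self.acc_b, self.try_b, 0.25)
        self._reset_counters()

    # -- update steps -------------------------------------------------------

    def _update_missing(self, rng: np.random.Generator) -> None:
        p, d = self.p, self.data
        self._dirty_cols: set = set()
        for j in self.miss_cols:
            rows = self.miss_rows[j]
            nr = len(rows)
            delta = np.zeros(nr)
            theta = p.theta_miss[j]
            plan = self._miss_plan[j]
            for k in range(4):
                bkj = p.gamma[j] * p.beta[k, j]
                if bkj == 0.0:
                    continue
                midx, sel = plan[k]
                if len(sel) == 0:
                    continue
                xc = self.X[rows[midx], j]
                y = d.y[k][sel]
                mu = self.mu[k][sel]
                sig = p.sigma_resid[k]
                buf = np.empty(len(sel))
                if k == 0:
                    lk.normal_miss_delta(y, mu, xc, bkj, sig, buf)
                else:
                    lo, hi = d.support[k]
                    lk.trunc_miss_delta(y, mu, xc, bkj, sig, lo, hi,
                                        self.lz[k][sel], buf)
                delta[midx] += buf
            logit1 = math.log(theta / (1.0 - theta)) + delta
            with np.errstate(over="ignore"):  # exp overflow -> p1 = 0 exactly
                p1 = 1.0 / (1.0 + np.exp(-logit1))
            new = (rng.uniform(size=nr) < p1).astype(float)
            old = self.X[rows, j]
            ch = new != old
            if not ch.any():
                continue
            self.X[rows[ch], j] = new[ch]
            self._dirty_cols.add(j)
            dx = (new - old)[ch]
            for k in range(4):
                pos = d.pos_in_k[k, rows[ch]]
                m = pos >= 0
                self._Xk[k][pos[m], j] = new[ch][m]
            for k in range(4):
                bkj = p.gamma[j] * p.beta[k, j]
                if bkj == 0.0:
                    continue
                pos = d.pos_in_k[k, rows[ch]]
                m = pos >= 0
                self.mu[k][pos[m]] += bkj * dx[m]
                if k > 0:
                    mc = m & ~_safe_at_best(d.at_best[k], pos)
                    tc = pos[mc]
                    if len(tc):
                        lo, hi = d.support[k]
                        self.lz[k][tc] = lk.log_trunc_z_vec(
                            self.mu[k][tc], p.sigma_resid[k], lo, hi)

    def _update_theta(self, rng: np.random.Generator) -> None:
        pri = self.config.priors
        n = self.data.n_visits
        for j in range(self.config.n_covariates):
            s1 = float(self.X[:, j].sum())
            self.p.theta_miss[j] = rng.beta(pri.miss_prior_a + s1,
                                            pri.miss_prior_b + n - s1)

    def _update_beta_ck(self, rng: np.random.Generator) -> None:
        p, d = self.p, self.data
        idx = d.idx[0]
        act = np.nonzero(p.gamma == 1)[0]
        D = np.column_stack([np.ones(len(idx)), d.t_k[0], self._Xk[0][:, act]])
        r = d.y[0] - p.b[d.pid_k[0], 0] - p.s[d.pid_k[0]] * d.t_k[0]
        m = D.shape[1]
        prec0 = np.concatenate([[self.prior_prec_int, self.prior_prec_time],
                                np.full(len(act), self.prior_prec_slab)])
        m0 = np.zeros(m)
        m0[0] = self.config.priors.intercept_prior_mean[0]
        s2 = p.sigma_resid[0] ** 2
        A = D.T @ D / s2 + np.diag(prec0)
        rhs = D.T @ r / s2 + prec0 * m0
        cf = cho_factor(A, lower=True)
        mean = cho_solve(cf, rhs)
        z = rng.normal(size=m)
        draw = mean + solve_triangular(cf[0].T, z, lower=False)
        p.beta0[0] = draw[0]
        p.beta_time[0] = draw[1]
        p.beta[0, :] = 0.0
        p.beta[0, act] = draw[2:]
        self.mu[0] = D @ draw + p.b[d.pid_k[0], 0] + p.s[d.pid_k[0]] * d.t_k[0]

    def _update_beta_hurdle(self, rng: np.random.Generator) -> None:
        p, d = self.p, self.data
        pri = self.config.priors
        for h, k in enumerate(_HURDLE_K):
            ci = self.cont_idx[k]
            if len(ci) == 0:
                continue
            sig = p.sigma_resid[k]
            lo, hi = d.support[k]
            yc = self.y_c[k]
            buf = self._lzbuf[k][:len(ci)]
            # intercept (scalar mean shift on all continuous rows)
            dlt = self.sc_beta[h, 0] * rng.normal()
            dll = lk.trunc_delta_scalar(yc, self.mu[k][ci], dlt, sig, lo, hi,
                                        self.lz[k][ci], buf)
            pm = pri.intercept_prior_mean[k]
            lpr = -0.5 * self.prior_prec_int * (
                (p.beta0[k] + dlt - pm) ** 2 - (p.beta0[k] - pm) ** 2)
            self.try_beta[h, 0] += 1
            if math.log(rng.uniform()) < dll + lpr:
                self.acc_beta[h, 0] += 1
                p.beta0[k] += dlt
                self.mu[k] += dlt
                self.lz[k][ci] = buf
            # time slope (per-row shift dlt * t)
            dlt = self.sc_beta[h, 1] * rng.normal()
            dll = lk.trunc_delta_vec(yc, self.mu[k][ci], dlt * d.t_k[k][ci],
                                     sig, lo, hi, self.lz[k][ci], buf)
            lpr = -0.5 * self.prior_prec_time * (
                (p.beta_time[k] + dlt) ** 2 - p.beta_time[k] ** 2)
            self.try_beta[h, 1] += 1
            if math.log(rng.uniform()) < dll + lpr:
                self.acc_beta[h, 1] += 1
                p.beta_time[k] += dlt
                self.mu[k] += dlt * d.t_k[k]
                self.lz[k][ci] = buf
            # active covariates (binary: scalar shift on their x=1 rows)
            Xk = self._Xk[k]
            for j in np.nonzero(p.gamma == 1)[0]:
                sub = self._xsub[k][j]
                dlt = self.sc_beta[h, 2 + j] * rng.normal()
                self.try_beta[h, 2 + j] += 1
                lpr = -0.5 * self.prior_prec_slab * (
                    (p.beta[k, j] + dlt) ** 2 - p.beta[k, j] ** 2)
                if len(sub):
                    bj = self._lzbuf[k][:len(sub)]
                    dll = lk.trunc_delta_scalar(
                        d.y[k][sub], self.mu[k][sub], dlt, sig, lo, hi,
                        self.lz[k][sub], bj)
                else:
                    bj = None
                    dll = 0.0
                if math.log(rng.uniform()) < dll + lpr:
                    self.acc_beta[h, 2 + j] += 1
                    p.beta[k, j] += dlt
                    self.mu[k] += dlt * Xk[:, j]
                    if bj is not None:
                        self.lz[k][sub] = bj

    def _delta_ll_column(self, j: int, beta_col: np.ndarray, sign: float):
        """Log-likelihood change from adding (sign=+1) / removing (sign=-1)
        covariate j with outcome coefficients beta_col.

        Returns (delta, lz_updates); the caller applies the recorded
        normalising-constant updates only on acceptance.
        """
        p, d = self.p, self.data
        total = 0.0
        lz_updates: list[tuple[int, np.ndarray, np.ndarray]] = []
        for k in range(4):
            bkj = sign * beta_col[k]
            if bkj == 0.0:
                continue
            sub = self._xsub[k][j]
            if k == 0:
                if len(sub):
                    total += lk.normal_delta_scalar(
                        d.y[0][sub], self.mu[0][sub], bkj, p.sigma_resid[0])
            else:
                if len(sub) == 0:
                    continue
                lo, hi = d.support[k]
                buf = self._lzbuf[k][:len(sub)]
                total += lk.trunc_delta_scalar(
                    d.y[k][sub], self.mu[k][sub], bkj, p.sigma_resid[k],
                    lo, hi, self.lz[k][sub], buf)
                lz_updates.append((k, sub, buf))
        return total, lz_updates

    def _update_gamma(self, rng: np.random.Generator) -> None:
        p, d = self.p, self.data
        slab_sd = self.config.priors.beta_slab_sd
        for j in self.sel_cols:
            if j in self._frozen_cols:
                continue
            if p.gamma[j] == 1:
                dll, lzu = self._delta_ll_column(j, p.beta[:, j], -1.0)
                if math.log(rng.uniform()) < dll - self.log_odds_inc:
                    old = p.beta[:, j].copy()
                    p.gamma[j] = 0
                    p.beta[:, j] = 0.0
                    for k in range(4):
                        if old[k] != 0.0:
                            self.mu[k] -= old[k] * self._Xk[k][:, j]
                    for k, sub, buf in lzu:
                        self.lz[k][sub] = buf
            else:
                prop = rng.normal(0.0, slab_sd, size=4)
                dll, lzu = self._delta_ll_column(j, prop, +1.0)
                if math.log(rng.uniform()) < dll + self.log_odds_inc:
                    p.gamma[j] = 1
                    p.beta[:, j] = prop
                    for k in range(4):
                        self.mu[k] += prop[k] * self._Xk[k][:, j]
                    for k, sub, buf in lzu:
                        self.lz[k][sub] = buf

    def _update_alpha(self, rng: np.random.Generator) -> None:
        p, d = self.p, self.data
        prec = 1.0 / self.config.priors.alpha_prior_sd ** 2
        n_coords = 3 if self.config.hurdle_random_intercept_loading else 2
        for h, k in enumerate(_HURDLE_K):
            ab = d.at_best[k]
            for ci in range(n_coords):
                delta = self.sc_alpha[h, ci] * rng.normal()
                if ci == 0:
                    dll = lk.bern_delta_scalar(ab, self.eta[h], delta)
                    shift = None
                else:
                    feat = d.t_k[k] if ci == 1 else p.b[d.pid_k[k], k]
                    shift = delta * feat
                    dll = lk.bern_delta_vec(ab, self.eta[h], shift)
                new_val = p.alpha[h, ci] + delta
                lpr = -0.5 * prec * (new_val ** 2 - p.alpha[h, ci] ** 2)
                self.try_alpha[h, ci] += 1
                if math.log(rng.uniform()) < dll + lpr:
                    self.acc_alpha[h, ci] += 1
                    p.alpha[h, ci] = new_val
                    if shift is None:
                        self.eta[h] = self.eta[h] + delta
                    else:
                        self.eta[h] = self.eta[h] + shift

    def _update_random_effects(self, rng: np.random.Generator) -> None:
        p, d = self.p, self.data
        N = d.n_patients
        z = rng.normal(size=(N, 5))
        db = self.sc_b[:, None] * z[:, :4]
        ds = self.sc_b * 0.2 * z[:, 4]
        dll = np.zeros(N)
        # CK: intercept + slope shift
        shift0 = db[d.pid_k[0], 0] + ds[d.pid_k[0]] * d.t_k[0]
        diff0 = self._dbuf[0][:len(d.y[0])]
        lk.normal_delta_rows(d.y[0], self.mu[0], shift0, p.sigma_resid[0], diff0)
        dll += np.bincount(d.pid_k[0], weights=diff0, minlength=N)
        loading = self.config.hurdle_random_intercept_loading
        lz_new: dict[int, np.ndarray] = {}
        for h, k in enumerate(_HURDLE_K):
            ab = d.at_best[k]
            ci = self.cont_idx[k]
            shift = db[d.pid_k[k], k]
            lo, hi = d.support[k]
            lzb = self._lzbuf[k][:len(ci)]
            dfb = self._dbuf[k][:len(ci)]
            lk.trunc_delta_rows(d.y[k][ci], self.mu[k][ci], shift[ci],
                                p.sigma_resid[k], lo, hi, self.lz[k][ci],
                                lzb, dfb)
            lz_new[k] = lzb
            dll += np.bincount(d.pid_k[k][ci], weights=dfb, minlength=N)
            if loading:
                eta_shift = p.alpha[h, 2] * shift
                diffb = self._dbuf[k]
                lk.bern_delta_rows(ab, self.eta[h], eta_shift, diffb)
                dll += np.bincount(d.pid_k[k], weights=diffb, minlength=N)
        # prior change
        L = cholesky(p.Sigma, lower=True)
        q_old = np.sum(solve_triangular(L, p.b.T, lower=True) ** 2, axis=0)
        q_new = np.sum(solve_triangular(L, (p.b + db).T, lower=True) ** 2, axis=0)
        dprior = -0.5 * (q_new - q_old)
        tau = max(p.tau_slope, 1e-12)
        dprior += -0.5 * ((p.s + ds) ** 2 - p.s ** 2) / tau
        acc = np.log(rng.uniform(size=N)) < dll + dprior
        self.try_b += 1
        self.acc_b += acc
        if not acc.any():
            return
        p.b[acc] += db[acc]
        p.s[acc] += ds[acc]
        acc0 = acc[d.pid_k[0]]
        self.mu[0][acc0] += shift0[acc0]
        for h, k in enumerate(_HURDLE_K):
            acck = acc[d.pid_k[k]]
            self.mu[k][acck] += db[d.pid_k[k], k][acck]
            ci = self.cont_idx[k]
            mc = acck[ci]
            self.lz[k][ci[mc]] = lz_new[k][mc]
            if loading:
                self.eta[h][acck] += p.alpha[h, 2] * db[d.pid_k[k], k][acck]

    def _update_sigma_matrix(self, rng: np.random.Generator) -> None:
        pri = self.config.priors
        p = self.p
        N = self.data.n_patients
        scale = pri.sigma_prior_scale * np.eye(4) + p.b.T @ p.b
        p.Sigma = invwishart.rvs(df=pri.sigma_prior_df + N, scale=scale,
                                 random_state=rng)

    def _update_tau(self, rng: np.random.Generator) -> None:
        pri = self.config.priors
        p = self.p
        a_post = pri.tau_prior_shape + self.data.n_patients / 2.0
        b_post = pri.tau_prior_scale + 0.5 * float(np.sum(p.s ** 2))
        p.tau_slope = b_post / rng.standard_gamma(a_post)

    def _update_sigma_resid(self, rng: np.random.Generator) -> None:
        p, d = self.p, self.data
        hs = self.config.priors.sigma_resid_halfnormal_scale
        for k in range(4):
            sig = p.sigma_resid[k]
            delta = self.sc_lsig[k] * rng.normal()
            sig_new = sig * math.exp(delta)
            buf = None
            if k == 0:
                dll = (lk.normal_ll_sum(d.y[0], self.mu[0], sig_new)
                       - lk.normal_ll_sum(d.y[0], self.mu[0], sig))
            else:
                ci = self.cont_idx[k]
                lo, hi = d.support[k]
                buf = self._lzbuf[k][:len(ci)]
                dll = lk.trunc_sigma_delta(d.y[k][ci], self.mu[k][ci], sig,
                                           sig_new, lo, hi, self.lz[k][ci], buf)
            lpr = -0.5 * (sig_new ** 2 - sig ** 2) / hs ** 2 + delta
            self.try_lsig[k] += 1
            if math.log(rng.uniform()) < dll + lpr:
                self.acc_lsig[k] += 1
                p.sigma_resid[k] = sig_new
                if buf is not None:
                    self.lz[k][self.cont_idx[k]] = buf

    _frozen_cols: frozenset = frozenset()

    def freeze_columns(self, names: list[str]) -> None:
        """Permanently exclude covariates (e.g. constant columns) from gamma."""
        idx = [self.config.covariate_names.index(n) for n in names]
        self._frozen_cols = frozenset(idx)

    def sweep(self, rng: np.random.Generator, adapt: bool = False) -> None:
        if self.config.impute_missing:
            self._update_missing(rng)
            if self._dirty_cols:
                self._precompute_subsets(sorted(self._dirty_cols))
        self._update_theta(rng)
        self._update_beta_ck(rng)
        self._update_beta_hurdle(rng)
        self._update_gamma(rng)
        self._update_alpha(rng)
        for _ in range(self.mcmc.n_re_updates):
            self._update_random_effects(rng)
        self._update_sigma_matrix(rng)
        self._update_tau(rng)
        self._update_sigma_resid(rng)
        self._adapt_countdown = getattr(self, "_adapt_countdown", 0) + 1
        if adapt and self._adapt_countdown % self.mcmc.adapt_window == 0:
            self._adapt_scales()

    def missing_values(self) -> np.ndarray:
        return np.array([self.X[r, j] for r, j in self.miss_cells])


def _safe_at_best(at_best: np.ndarray, pos: np.ndarray) -> np.ndarray:
    out = np.zeros(len(pos), bool)
    ok = pos >= 0
    out[ok] = at_best[pos[ok]]
    return out


# ---------------------------------------------------------------------------
# Draw container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Thinned posterior draws, shape (n_chains, n_draws_per_chain, ...)."""

    beta0: np.ndarray
    beta_time: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    Sigma: np.ndarray
    tau_slope: np.ndarray
    sigma_resid: np.ndarray
    theta_miss: np.ndarray
    b: np.ndarray
    s: np.ndarray
    x_miss: np.ndarray                # (C, D, n_missing_cells)
    miss_cells: list[tuple[int, int]]
    covariate_names: list[str]
    mcmc: McmcConfig
    diagnostics: "object | None" = None
    converged: bool | None = None

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[0] * self.beta0.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def to_dataframe(self):
        """Flat columnar table of the scalar model parameters per draw."""
        import pandas as pd

        cols = {}
        for k, on in enumerate(OUTCOME_NAMES):
            cols[f"beta0[{on}]"] = self.stacked("beta0")[:, k]
            cols[f"beta_time[{on}]"] = self.stacked("beta_time")[:, k]
            cols[f"sigma_resid[{on}]"] = self.stacked("sigma_resid")[:, k]
            for j, cn in enumerate(self.covariate_names):
                cols[f"beta[{on}][{cn}]"] = self.stacked("beta")[:, k, j]
        for j, cn in enumerate(self.covariate_names):
            cols[f"gamma[{cn}]"] = self.stacked("gamma")[:, j]
            cols[f"theta[{cn}]"] = self.stacked("theta_miss")[:, j]
        for h, on in enumerate(HURDLE_NAMES):
            for ci, cn in enumerate(("int", "time", "loading")):
                cols[f"alpha[{on}][{cn}]"] = self.stacked("alpha")[:, h, ci]
        for a in range(4):
            for bb in range(a, 4):
                cols[f"Sigma[{a}][{bb}]"] = self.stacked("Sigma")[:, a, bb]
        cols["tau_slope"] = self.stacked("tau_slope")
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains),
                                        self.beta0.shape[1]))
        df.insert(1, "draw", np.tile(np.arange(self.beta0.shape[1]),
                                     self.n_chains))
        return df

    def inclusion_probabilities(self) -> dict[str, float]:
        g = self.stacked("gamma")
        return {n: float(g[:, j].mean())
                for j, n in enumerate(self.covariate_names)}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit(cohort: Cohort, config: ModelConfig, mcmc: McmcConfig,
        progress: bool = False) -> PosteriorDraws:
    """Run the full MCMC and return thinned posterior draws.

    The cohort must already have complete history covariates (run
    `filter_history_complete`).  Chains are independent, each seeded from
    `SeedSequence(mcmc.seed)`; identical seed/config reproduce bit-identical
    draws.
    """
    data = ModelData(cohort, config)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    store: dict[str, list] = {n: [] for n in (
        "beta0", "beta_time", "beta", "alpha", "gamma", "Sigma", "tau_slope",
        "sigma_resid", "theta_miss", "b", "s", "x_miss")}
    sampler = None
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        params, X0, dropped = _initialize(data, config, rng)
        sampler = GibbsSampler(data, config, mcmc)
        if dropped:
            sampler.freeze_columns(dropped)
        sampler.set_state(params, X0)
        sampler._abort_if_nonfinite()
        chain = {n: [] for n in store}
        for it in range(mcmc.n_iterations):
            sampler.sweep(rng, adapt=(it < mcmc.n_burnin and mcmc.adapt))
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                p = sampler.p
                chain["beta0"].append(p.beta0.copy())
                chain["beta_time"].append(p.beta_time.copy())
                chain["beta"].append((p.gamma * p.beta).copy())
                chain["alpha"].append(p.alpha.copy())
                chain["gamma"].append(p.gamma.copy())
                chain["Sigma"].append(p.Sigma.copy())
                chain["tau_slope"].append(p.tau_slope)
                chain["sigma_resid"].append(p.sigma_resid.copy())
                chain["theta_miss"].append(p.theta_miss.copy())
                chain["b"].append(p.b.copy())
                chain["s"].append(p.s.copy())
                chain["x_miss"].append(sampler.missing_values())
            if progress and (it + 1) % 500 == 0:
                print(f"chain {c}: iteration {it + 1}/{mcmc.n_iterations}")
        for n in store:
            store[n].append(np.array(chain[n]))
    draws = PosteriorDraws(
        **{n: np.stack(store[n]) for n in store},
        miss_cells=sampler.miss_cells,
        covariate_names=config.covariate_names,
        mcmc=mcmc,
    )
    diag = convergence_report(draws)
    draws.diagnostics = diag
    draws.converged = bool((diag["rhat"] <= mcmc.rhat_threshold).all())
    if not draws.converged:
        warnings.warn("chains flagged as not converged (split-Rhat above "
                      f"{mcmc.rhat_threshold}); results retained with flag",
                      stacklevel=2)
    return draws


def convergence_report(draws: PosteriorDraws):
    """Split-Rhat and effective sample size for the scalar model parameters.

    With a single chain the chain is split in half first (documented caveat:
    this detects slow drift, not multimodality across starts).
    """
    import pandas as pd

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        rows = []
        for name, arr, labels in _scalar_views(draws):
            a = arr
            if a.shape[0] == 1:  # single chain: split into halves
                half = a.shape[1] // 2
                a = np.stack([a[0, :half], a[0, half:2 * half]])
            for idx, label in labels:
                series = a[(slice(None), slice(None)) + idx]
                if np.allclose(series.var(), 0.0):
                    rhat, ess = 1.0, float(series.size)
                else:
                    rhat = float(az.rhat(series))
                    ess = float(az.ess(series))
                rows.append({"parameter": label, "rhat": rhat, "ess": ess})
    df = pd.DataFrame(rows)
    df["flagged"] = (df["rhat"] > draws.mcmc.rhat_threshold) | (
        df["ess"] < draws.mcmc.ess_threshold)
    return df


def _scalar_views(draws: PosteriorDraws):
    covs = draws.covariate_names
    yield ("beta0", draws.beta0,
           [((k,), f"beta0[{on}]") for k, on in enumerate(OUTCOME_NAMES)])
    yield ("beta_time", draws.beta_time,
           [((k,), f"beta_time[{on}]") for k, on in enumerate(OUTCOME_NAMES)])
    labels = []
    for k, on in enumerate(OUTCOME_NAMES):
        for j, cn in enumerate(covs):
            labels.append(((k, j), f"beta[{on}][{cn}]"))
    yield ("beta", draws.beta, labels)
    yield ("sigma_resid", draws.sigma_resid,
           [((k,), f"sigma_resid[{on}]") for k, on in enumerate(OUTCOME_NAMES)])
    labels = []
    for h, on in enumerate(HURDLE_NAMES):
        for ci, cn in enumerate(("int", "time", "loading")):
            labels.append(((h, ci), f"alpha[{on}][{cn}]"))
    yield ("alpha", draws.alpha, labels)
    labels = [((a, bb), f"Sigma[{a}][{bb}]")
              for a in range(4) for bb in range(a, 4)]
    yield ("Sigma", draws.Sigma, labels)
    yield ("tau_slope", draws.tau_slope, [((), "tau_slope")])
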