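"""Low-level log-likelihood kernels.

The joint model needs three per-visit densities, evaluated millions of times
inside the Gibbs sweep:

* Gaussian log-density (log CK given its linear predictor);
* Gaussian log-density truncated to the continuous-branch support of a hurdle
  outcome (sqrt CMAS/MMT8/PGA strictly away from the best value);
* Bernoulli log-likelihood of the hurdle indicator under a logistic
  probability.

Besides plain density sums, the module provides fused *delta* kernels that
return the log-likelihood change of a Metropolis proposal in a single pass.
The truncated-Gaussian deltas take the cached per-row normalising constant
log(Phi(b) - Phi(a)) of the current state and emit the proposal's constants,
so each proposal costs one erfc pair per row instead of two.

All kernels are written as plain loops and jit-compiled with numba when it is
available; the same functions run as pure Python otherwise, keeping the
package importable without numba.  The truncation constant is computed with
erfc branches so both tails stay accurate.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

_LOG_2PI = math.log(2.0 * math.pi)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_TINY = 1e-300


def _log_phi_interval(a: float, b: float) -> float:
    """log(Phi(b) - Phi(a)) for a < b, stable in both tails."""
    if a > 0.0:
        z = 0.5 * (math.erfc(a * _INV_SQRT2) - math.erfc(b * _INV_SQRT2))
    elif b < 0.0:
        z = 0.5 * (math.erfc(-b * _INV_SQRT2) - math.erfc(-a * _INV_SQRT2))
    else:
        z = 1.0 - 0.5 * math.erfc(b * _INV_SQRT2) - 0.5 * math.erfc(-a * _INV_SQRT2)
    if z < _TINY:
        z = _TINY
    return math.log(z)


if HAVE_NUMBA:
    _log_phi_interval = njit(cache=True)(_log_phi_interval)


def _jit(fn):
    return njit(cache=True)(fn) if HAVE_NUMBA else fn


# ---------------------------------------------------------------------------
# Density sums / vectors
# ---------------------------------------------------------------------------

@_jit
def normal_ll_vec(y, mu, sigma):
    out = np.empty(y.shape[0])
    inv = 1.0 / sigma
    c = -math.log(sigma) - 0.5 * _LOG_2PI
    for i in range(y.shape[0]):
        z = (y[i] - mu[i]) * inv
        out[i] = c - 0.5 * z * z
    return out


@_jit
def trunc_ll_vec(y, mu, sigma, lo, hi):
    out = np.empty(y.shape[0])
    inv = 1.0 / sigma
    c = -math.log(sigma) - 0.5 * _LOG_2PI
    for i in range(y.shape[0]):
        z = (y[i] - mu[i]) * inv
        a = (lo - mu[i]) * inv
        b = (hi - mu[i]) * inv
        out[i] = c - 0.5 * z * z - _log_phi_interval(a, b)
    return out


@_jit
def bern_ll_vec(at_best, eta):
    out = np.empty(eta.shape[0])
    for i in range(eta.shape[0]):
        e = eta[i]
        if e > 0.0:
            ls_pos = -math.log1p(math.exp(-e))   # log sigmoid(eta)
            ls_neg = -e + ls_pos                 # log sigmoid(-eta)
        else:
            ls_neg = -math.log1p(math.exp(e))
            ls_pos = e + ls_neg
        out[i] = ls_pos if at_best[i] else ls_neg
    return out


@_jit
def log_trunc_z_vec(mu, sigma, lo, hi):
    out = np.empty(mu.shape[0])
    inv = 1.0 / sigma
    for i in range(mu.shape[0]):
        out[i] = _log_phi_interval((lo - mu[i]) * inv, (hi - mu[i]) * inv)
    return out


# ---------------------------------------------------------------------------
# Metropolis delta kernels (log-lik change of a proposal, single pass)
# ---------------------------------------------------------------------------

@_jit
def normal_delta_scalar(y, mu, d, sigma):
    """Sum of Gaussian log-lik changes when every mu shifts by scalar d."""
    inv2 = 1.0 / (sigma * sigma)
    tot = 0.0
    for i in range(y.shape[0]):
        r = y[i] - mu[i]
        tot += (d * r - 0.5 * d * d) * inv2
    return tot


@_jit
def normal_delta_rows(y, mu, shift, sigma, diff):
    """Per-row Gaussian log-lik change under per-row shifts (fills diff)."""
    inv2 = 1.0 / (sigma * sigma)
    for i in range(y.shape[0]):
        d = shift[i]
        r = y[i] - mu[i]
        diff[i] = (d * r - 0.5 * d * d) * inv2


@_jit
def trunc_delta_scalar(y, mu, d, sigma, lo, hi, lz, lz_new):
    """Truncated-Gaussian log-lik change under a scalar mean shift.

    ``lz`` holds the current per-row log normalising constants; the
    proposal's constants are written to ``lz_new`` (apply on acceptance).
    """
    inv = 1.0 / sigma
    inv2 = inv * inv
    tot = 0.0
    for i in range(y.shape[0]):
        m = mu[i] + d
        r = y[i] - mu[i]
        zn = _log_phi_interval((lo - m) * inv, (hi - m) * inv)
        lz_new[i] = zn
        tot += (d * r - 0.5 * d * d) * inv2 - (zn - lz[i])
    return tot


@_jit
def trunc_delta_vec(y, mu, shift, sigma, lo, hi, lz, lz_new):
    """As trunc_delta_scalar with a per-row shift vector; returns the sum."""
    inv = 1.0 / sigma
    inv2 = inv * inv
    tot = 0.0
    for i in range(y.shape[0]):
        d = shift[i]
        m = mu[i] + d
        r = y[i] - mu[i]
        zn = _log_phi_interval((lo - m) * inv, (hi - m) * inv)
        lz_new[i] = zn
        tot += (d * r - 0.5 * d * d) * inv2 - (zn - lz[i])
    return tot


@_jit
def trunc_delta_rows(y, mu, shift, sigma, lo, hi, lz, lz_new, diff):
    """Per-row truncated-Gaussian delta under per-row shifts (fills diff)."""
    inv = 1.0 / sigma
    inv2 = inv * inv
    for i in range(y.shape[0]):
        d = shift[i]
        m = mu[i] + d
        r = y[i] - mu[i]
        zn = _log_phi_interval((lo - m) * inv, (hi - m) * inv)
        lz_new[i] = zn
        diff[i] = (d * r - 0.5 * d * d) * inv2 - (zn - lz[i])


@_jit
def trunc_sigma_delta(y, mu, sig, sig_new, lo, hi, lz, lz_new):
    """Truncated-Gaussian log-lik change when sigma changes (mu fixed)."""
    inv_o = 1.0 / sig
    inv_n = 1.0 / sig_new
    cd = math.log(sig) - math.log(sig_new)
    tot = 0.0
    for i in range(y.shape[0]):
        r = y[i] - mu[i]
        zn = _log_phi_interval((lo - mu[i]) * inv_n, (hi - mu[i]) * inv_n)
        lz_new[i] = zn
        tot += cd - 0.5 * r * r * (inv_n * inv_n - inv_o * inv_o) - (zn - lz[i])
    return tot


@_jit
def normal_miss_delta(y, mu, xc, bkj, sigma, diff):
    """Per-row Gaussian log-lik(x=1) - log-lik(x=0); mu matches current xc."""
    inv2 = 1.0 / (sigma * sigma)
    for i in range(y.shape[0]):
        m1 = mu[i] + (1.0 - xc[i]) * bkj
        m0 = m1 - bkj
        r1 = y[i] - m1
        r0 = y[i] - m0
        diff[i] = 0.5 * (r0 * r0 - r1 * r1) * inv2


@_jit
def trunc_miss_delta(y, mu, xc, bkj, sigma, lo, hi, lz, diff):
    """Per-row truncated log-lik(x=1) - log-lik(x=0), reusing the cached
    normalising constant of whichever side equals the current state."""
    inv = 1.0 / sigma
    inv2 = inv * inv
    for i in range(y.shape[0]):
        m1 = mu[i] + (1.0 - xc[i]) * bkj
        m0 = m1 - bkj
        if xc[i] > 0.5:
            z1 = lz[i]
            z0 = _log_phi_interval((lo - m0) * inv, (hi - m0) * inv)
        else:
            z0 = lz[i]
            z1 = _log_phi_interval((lo - m1) * inv, (hi - m1) * inv)
        r1 = y[i] - m1
        r0 = y[i] - m0
        diff[i] = 0.5 * (r0 * r0 - r1 * r1) * inv2 - (z1 - z0)


@_jit
def bern_delta_scalar(at_best, eta, d):
    """Sum of Bernoulli log-lik changes when every logit shifts by d."""
    tot = 0.0
    for i in range(eta.shape[0]):
        tot += _bern_ll_one(at_best[i], eta[i] + d) - _bern_ll_one(at_best[i], eta[i])
    return tot


@_jit
def bern_delta_vec(at_best, eta, shift):
    tot = 0.0
    for i in range(eta.shape[0]):
        tot += (_bern_ll_one(at_best[i], eta[i] + shift[i])
                - _bern_ll_one(at_best[i], eta[i]))
    return tot


@_jit
def bern_delta_rows(at_best, eta, shift, diff):
    for i in range(eta.shape[0]):
        diff[i] = (_bern_ll_one(at_best[i], eta[i] + shift[i])
                   - _bern_ll_one(at_best[i], eta[i]))


def _bern_ll_one(ab: bool, e: float) -> float:
    if e > 0.0:
        ls_pos = -math.log1p(math.exp(-e))
        ls_neg = -e + ls_pos
    else:
        ls_neg = -math.log1p(math.exp(e))
        ls_pos = e + ls_neg
    return ls_pos if ab else ls_neg


if HAVE_NUMBA:
    # numba compiles lazily, so the jitted kernels above resolve this global
    # to the dispatcher at their first call
    _bern_ll_one = njit(cache=True)(_bern_ll_one)


# ---------------------------------------------------------------------------
# Convenience sums
# ---------------------------------------------------------------------------

def normal_ll_sum(y, mu, sigma) -> float:
    return float(np.sum(normal_ll_vec(y, mu, sigma)))


def trunc_ll_sum(y, mu, sigma, lo, hi) -> float:
    return float(np.sum(trunc_ll_vec(y, mu, sigma, lo, hi)))


def bern_ll_sum(at_best, eta) -> float:
    return float(np.sum(bern_ll_vec(at_best, eta)))


def log_phi_interval(a: float, b: float) -> float:
    """Public scalar wrapper (used by the single-visit likelihood)."""
    return float(_log_phi_interval(a, b))
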