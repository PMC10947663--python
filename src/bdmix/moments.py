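"""Closed-form moments of the birth-death mixture.

For one subpopulation with net growth rate lambda(d) = beta - nu(d) and
initial size n_p, the linear birth-death process X(t) has

    E[X(t)]   = n_p * exp(lambda t)
    Var[X(t)] = n_p * (beta + nu(d)) / lambda * (e^{2 lambda t} - e^{lambda t})

with the critical-case limit Var = n_p (beta + nu) t as lambda -> 0.

For live-cell imaging the same well is observed on a time grid, so counts
are correlated across time.  The centered-scaled total count converges (as
the initial count n grows) to a zero-mean Gaussian vector whose covariance
on a grid 0 < t_1 < ... < t_N is

    Sigma_{i,j} = sum_{l=1}^{min(i,j)} sum_k p_k
                  e^{lambda_k (t_i - t_l)} e^{lambda_k (t_j - t_l)}
                  e^{lambda_k t_{l-1}} sigma_k^2(t_l - t_{l-1}),

where sigma_k^2(tau) is the per-cell variance factor above and t_0 = 0.
The diagonal of Sigma telescopes back to the marginal variances, which is
used as a consistency check in the tests.
"""

from __future__ import annotations

import numpy as np

from .core_model import MixtureModel, Subpopulation, rates

__all__ = ["subpop_moments", "mixture_moments", "covariance_matrix",
           "batch_moments", "batch_covariance"]

# below this |lambda * t| the variance factor switches to its lambda -> 0 limit
_CRITICAL_SWITCH = 1e-8


def _var_factor(t, beta: float, nu_d: float, lam: float):
    """Per-cell variance factor sigma^2(t) of one birth-death lineage."""
    t = np.asarray(t, dtype=float)
    lt = lam * t
    crit = np.abs(lt) < _CRITICAL_SWITCH
    # away from criticality; guard the lam=0 division on the branch not taken
    lam_safe = lam if lam != 0.0 else 1.0
    with np.errstate(over="ignore", invalid="ignore"):
        generic = (beta + nu_d) / lam_safe * (np.exp(2.0 * lt) - np.exp(lt))
    out = np.where(crit, (beta + nu_d) * t, generic)
    if out.ndim == 0:
        return float(out)
    return out


def subpop_moments(t, d, s: Subpopulation, np_init: float):
    """Mean and variance of one subpopulation's size at time t under dose d.

    np_init is the initial size of the subpopulation.  t may be a scalar or
    an array of non-negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be non-negative")
    if np_init < 0.0:
        raise ValueError("initial subpopulation size must be >= 0")
    death, lam = rates(d, s)
    mean = np_init * np.exp(lam * t)
    var = np_init * _var_factor(t, s.beta, death, lam)
    if mean.ndim == 0:
        return float(mean), float(var)
    return mean, var


def mixture_moments(t, d, model: MixtureModel):
    """Mean and (noise-free) variance of the total count at time t, dose d.

    Subpopulations are independent, so means and variances add, each
    started from n * p_i cells.
    """
    t = np.asarray(t, dtype=float)
    mu = np.zeros_like(t, dtype=float)
    var = np.zeros_like(t, dtype=float)
    for s in model.subpops:
        m_i, v_i = subpop_moments(t, d, s, model.n * s.p)
        mu = mu + m_i
        var = var + v_i
    if mu.ndim == 0:
        return float(mu), float(var)
    return mu, var


def batch_moments(times, doses, model: MixtureModel):
    """Mean and noise-free variance on a (dose, time) grid.

    Returns (mu, var), each of shape (N_D, N_T).  Equivalent to calling
    mixture_moments per dose but vectorized for the inner loop of fitting.
    """
    times = np.asarray(times, dtype=float)
    doses = np.asarray(doses, dtype=float)
    mu = np.zeros((doses.size, times.size))
    var = np.zeros_like(mu)
    for s in model.subpops:
        death, lam = rates(doses, s)                     # (N_D,)
        lt = lam[:, None] * times[None, :]               # (N_D, N_T)
        growth = np.exp(lt)
        np_init = model.n * s.p
        mu += np_init * growth
        crit = np.abs(lt) < _CRITICAL_SWITCH
        lam_safe = np.where(lam == 0.0, 1.0, lam)
        with np.errstate(over="ignore", invalid="ignore"):
            generic = ((s.beta + death) / lam_safe)[:, None] * (growth ** 2 - growth)
        var += np_init * np.where(crit, (s.beta + death)[:, None] * times[None, :],
                                  generic)
    return mu, var


def batch_covariance(times, doses, model: MixtureModel) -> np.ndarray:
    """Normalized-process covariance for every dose at once, (N_D, N_T, N_T)."""
    times = np.asarray(times, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if times[0] <= 0.0 or np.any(np.diff(times) <= 0.0):
        raise ValueError("times must be strictly increasing and positive")
    n_t = times.size
    t_prev = np.concatenate(([0.0], times[:-1]))
    dt = times - t_prev
    lower = (times[:, None] >= times[None, :]).astype(float)   # (N_T, N_T)
    sigma = np.zeros((doses.size, n_t, n_t))
    for s in model.subpops:
        death, lam = rates(doses, s)                           # (N_D,)
        ldt = lam[:, None] * dt[None, :]
        crit = np.abs(ldt) < _CRITICAL_SWITCH
        lam_safe = np.where(lam == 0.0, 1.0, lam)
        with np.errstate(over="ignore", invalid="ignore"):
            generic = ((s.beta + death) / lam_safe)[:, None] * (
                np.exp(2.0 * ldt) - np.exp(ldt))
        vf = np.where(crit, (s.beta + death)[:, None] * dt[None, :], generic)
        w = np.exp(lam[:, None] * t_prev[None, :]) * vf        # (N_D, N_T)
        a = np.exp(lam[:, None, None]
                   * (times[None, :, None] - times[None, None, :])) * lower
        sigma += s.p * np.einsum("dil,dl,djl->dij", a, w, a)
    return 0.5 * (sigma + sigma.transpose(0, 2, 1))


def covariance_matrix(times, d, model: MixtureModel) -> np.ndarray:
    """Covariance matrix of the normalized total-count process on a time grid.

    times must be strictly increasing and positive; the known start t_0 = 0
    (deterministic count n) is implicit and carries no variance.  Returns the
    N_T x N_T matrix Sigma of the centered process scaled by 1/sqrt(n); the
    covariance of the raw counts is n * Sigma.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-d grid")
    if times[0] <= 0.0 or np.any(np.diff(times) <= 0.0):
        raise ValueError("times must be strictly increasing and positive "
                         "(t = 0 is implicit and excluded)")
    n_t = times.size
    t_prev = np.concatenate(([0.0], times[:-1]))   # t_{l-1}
    dt = times - t_prev                            # increment lengths
    sigma = np.zeros((n_t, n_t))
    lower = times[:, None] >= times[None, :]       # l <= i mask
    for s in model.subpops:
        death, lam = rates(d, s)
        w = np.exp(lam * t_prev) * _var_factor(dt, s.beta, death, lam)
        # A[i, l] = e^{lam (t_i - t_l)} for l <= i, else 0
        a = np.where(lower, np.exp(lam * (times[:, None] - times[None, :])), 0.0)
        sigma += s.p * (a * w) @ a.T
    return 0.5 * (sigma + sigma.T)
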