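"""Log-likelihoods of the three statistical models.

All three treat the t = 0 observation as the known seeding count n, which
carries no stochastic variance, so only positive observation times enter.
Observations at different doses and from distinct replicates are independent
throughout; the models differ in the distribution of the per-well time
vector:

* phenopop  — deterministic exponential growth per subpopulation plus
  i.i.d. Gaussian noise with two variance levels (high at late times and
  low doses, low otherwise).
* endpoint  — each (t, d) observation is Gaussian with the birth-death
  mixture mean mu(t, d) and variance n sigma^2(t, d) + c^2; time points are
  independent (destructive counting).
* livecell  — the per-well time vector is multivariate Gaussian with mean
  mu(d) and covariance n Sigma(d) + c^2 I, capturing the positive time
  correlation of repeated imaging of the same well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .core_model import MixtureModel, PhenoPopParams, hill
from .moments import batch_covariance, batch_moments, covariance_matrix
from .simulate import Dataset

__all__ = ["LogLikResult", "loglik_phenopop", "loglik_endpoint", "loglik_livecell"]

_LOG_2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class LogLikResult:
    """A log-likelihood value with its per-dose decomposition.

    loglik equals per_dose.sum(); n_params is the number of free parameters
    of the evaluated model (used for information criteria).
    """

    loglik: float
    per_dose: np.ndarray
    n_params: int


def n_free_params_bd(S: int) -> int:
    """Free parameters of the birth-death mixture: 5 per subpopulation
    (beta, nu, b, E, m), S - 1 free fractions, and the noise SD c."""
    return 6 * S


def n_free_params_phenopop(S: int) -> int:
    """Free parameters of the two-level-noise exponential-growth model:
    4 per subpopulation (alpha, b, E, m), S - 1 fractions, two noise SDs."""
    return 5 * S + 1


def phenopop_mean(t, d, theta: PhenoPopParams, n: int):
    """Deterministic total count n * sum_i p_i exp(t (alpha_i + log H_i(d)))."""
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for p, a, hp in zip(theta.fractions, theta.alphas, theta.hills):
        total = total + p * np.exp(t * (a + np.log(hill(d, hp))))
    return n * total


def loglik_phenopop(theta: PhenoPopParams, data: Dataset) -> LogLikResult:
    """Gaussian log-likelihood of the two-level-noise growth model."""
    times = data.design.times_pos
    x = data.counts_pos  # (N_T-1, N_D, N_R)
    per_dose = np.zeros(len(data.design.doses))
    for k, d in enumerate(data.design.doses):
        mean = phenopop_mean(times, d, theta, data.n)
        high = (times >= theta.T_L) & (d <= theta.D_L)
        var = np.where(high, theta.sigma_H ** 2, theta.sigma_L ** 2)
        resid = x[:, k, :] - mean[:, None]
        ll = -0.5 * (_LOG_2PI + np.log(var[:, None]) + resid ** 2 / var[:, None])
        per_dose[k] = ll.sum()
    return LogLikResult(float(per_dose.sum()), per_dose, n_free_params_phenopop(theta.S))


def loglik_endpoint(theta: MixtureModel, data: Dataset) -> LogLikResult:
    """Gaussian log-likelihood under independent time points (end-point assay)."""
    times = data.design.times_pos
    x = data.counts_pos                                   # (N_T-1, N_D, N_R)
    mu, var = batch_moments(times, data.design.doses, theta)   # (N_D, N_T-1)
    total_var = np.maximum(var + theta.c ** 2, _VAR_FLOOR)
    resid = x - mu.T[:, :, None]
    ll = -0.5 * (_LOG_2PI + np.log(total_var.T[:, :, None])
                 + resid ** 2 / total_var.T[:, :, None])
    per_dose = ll.sum(axis=(0, 2))
    return LogLikResult(float(per_dose.sum()), per_dose, n_free_params_bd(theta.S))


def _chol_with_jitter(cov: np.ndarray, d: float):
    """Cholesky factorization with escalating diagonal jitter.

    Near-critical growth rates and long horizons can make n Sigma + c^2 I
    numerically singular; jitter starts at 1e-10 * trace and grows tenfold,
    at most three escalations, before giving up.
    """
    jitter = 0.0
    base = 1e-10 * np.trace(cov) / cov.shape[0]
    for attempt in range(4):
        try:
            return cho_factor(cov + jitter * np.eye(cov.shape[0]), lower=True)
        except LinAlgError:
            jitter = base * 10.0 ** attempt if jitter == 0.0 else jitter * 10.0
    raise LinAlgError(f"covariance factorization failed at dose {d} "
                      "after jitter escalation")


def loglik_livecell(theta: MixtureModel, data: Dataset) -> LogLikResult:
    """Multivariate Gaussian log-likelihood under time-correlated counts."""
    times = data.design.times_pos
    x = data.counts_pos
    n_t = times.size
    mu, _ = batch_moments(times, data.design.doses, theta)         # (N_D, N_T-1)
    cov = theta.n * batch_covariance(times, data.design.doses, theta)
    cov += (theta.c ** 2) * np.eye(n_t)[None, :, :]
    diag = np.arange(n_t)
    cov[:, diag, diag] = np.maximum(cov[:, diag, diag], _VAR_FLOOR)
    resid = np.transpose(x, (1, 0, 2)) - mu[:, :, None]            # (N_D, N_T-1, N_R)
    try:
        chol = np.linalg.cholesky(cov)                             # batched
        logdet = 2.0 * np.sum(np.log(chol[:, diag, diag]), axis=1)
        z = np.linalg.solve(chol, resid)
        quad = np.sum(z ** 2, axis=1)                              # (N_D, N_R)
    except np.linalg.LinAlgError:
        # rare ill-conditioned parameter points: per-dose jitter fallback
        logdet = np.empty(cov.shape[0])
        quad = np.empty((cov.shape[0], x.shape[2]))
        for k, d in enumerate(data.design.doses):
            factor = _chol_with_jitter(cov[k], d)
            logdet[k] = 2.0 * np.sum(np.log(np.diag(factor[0])))
            solved = cho_solve(factor, resid[k])
            quad[k] = np.sum(resid[k] * solved, axis=0)
    per_dose = np.sum(-0.5 * (n_t * _LOG_2PI + logdet[:, None] + quad), axis=1)
    return LogLikResult(float(per_dose.sum()), per_dose, n_free_params_bd(theta.S))
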