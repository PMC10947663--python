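"""The three log-likelihoods, checked against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import bdmix as bm
from bdmix.likelihood import loglik_endpoint, loglik_livecell, loglik_phenopop


def _dataset_from_counts(counts, times, doses, n, mode="livecell"):
    design = bm.ExperimentDesign(times=times, doses=doses,
                                 n_replicates=counts.shape[2], mode=mode)
    return bm.Dataset(counts=counts, design=design, n=n)


def test_phenopop_hand_computed_single_observation():
    """One observation, one clone: the Gaussian density evaluated by hand."""
    theta = bm.PhenoPopParams(fractions=(1.0,), alphas=(0.1,),
                              hills=(bm.HillParams(0.8, 1.0, 2.0),),
                              sigma_H=33.0, sigma_L=10.0, T_L=2.0, D_L=1.0)
    counts = np.zeros((2, 1, 1))
    counts[0, 0, 0] = 100.0
    counts[1, 0, 0] = 120.0
    data = _dataset_from_counts(counts, (0.0, 1.0), (0.0,), n=100)
    expected = norm.logpdf(120.0, loc=100.0 * np.exp(0.1), scale=10.0)
    result = loglik_phenopop(theta, data)
    assert result.loglik == pytest.approx(expected, rel=1e-12)
    # zero residual: only the normalizing constant remains
    counts[1, 0, 0] = 100.0 * np.exp(0.1)
    data2 = _dataset_from_counts(counts, (0.0, 1.0), (0.0,), n=100)
    assert loglik_phenopop(theta, data2).loglik == pytest.approx(
        -0.5 * np.log(2.0 * np.pi * 100.0), rel=1e-12)


def test_phenopop_two_level_variance_rule():
    """sigma_H applies at late times and low doses, sigma_L otherwise."""
    theta = bm.PhenoPopParams(fractions=(1.0,), alphas=(0.0,),
                              hills=(bm.HillParams(0.9, 1.0, 2.0),),
                              sigma_H=50.0, sigma_L=5.0, T_L=10.0, D_L=0.5)
    counts = np.full((3, 2, 1), 100.0)
    data = _dataset_from_counts(counts, (0.0, 5.0, 15.0), (0.1, 2.0), n=100)
    result = loglik_phenopop(theta, data)
    # brute-force the four (t, d) cells
    expected = 0.0
    for t in (5.0, 15.0):
        for d in (0.1, 2.0):
            sigma = 50.0 if (t >= 10.0 and d <= 0.5) else 5.0
            mean = 100.0 * bm.hill(d, theta.hills[0]) ** t
            expected += norm.logpdf(100.0, loc=mean, scale=sigma)
    assert result.loglik == pytest.approx(expected, rel=1e-12)


def test_replicate_permutation_invariance(case_study_model, small_livecell_data):
    data = small_livecell_data
    perm = np.random.default_rng(4).permutation(data.design.n_replicates)
    shuffled = bm.Dataset(counts=data.counts[:, :, perm], design=data.design,
                          n=data.n)
    for fn in (loglik_endpoint, loglik_livecell):
        assert fn(case_study_model, shuffled).loglik == pytest.approx(
            fn(case_study_model, data).loglik, rel=1e-12)


def test_dose_permutation_invariance(case_study_model, small_livecell_data):
    data = small_livecell_data
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(data.design.doses))
    design = bm.ExperimentDesign(times=data.design.times,
                                 doses=np.asarray(data.design.doses)[perm],
                                 n_replicates=data.design.n_replicates,
                                 mode=data.design.mode)
    shuffled = bm.Dataset(counts=data.counts[:, perm, :], design=design, n=data.n)
    res_a = loglik_livecell(case_study_model, data)
    res_b = loglik_livecell(case_study_model, shuffled)
    assert res_b.loglik == pytest.approx(res_a.loglik, rel=1e-12)
    np.testing.assert_allclose(res_b.per_dose, res_a.per_dose[perm], rtol=1e-12)


def test_endpoint_matches_livecell_at_single_time(case_study_model):
    rng = np.random.default_rng(6)
    design = bm.ExperimentDesign(times=(0.0, 12.0), doses=(0.0, 0.3, 3.0),
                                 n_replicates=5, mode="livecell")
    data = bm.simulate_dataset(case_study_model, design, rng)
    ep = loglik_endpoint(case_study_model, data)
    lc = loglik_livecell(case_study_model, data)
    assert lc.loglik == pytest.approx(ep.loglik, rel=1e-12)


def test_livecell_matches_multivariate_normal_oracle(case_study_model,
                                                     small_livecell_data):
    data = small_livecell_data
    model = case_study_model
    times = data.design.times_pos
    result = loglik_livecell(model, data)
    for k, d in enumerate(data.design.doses):
        mu, _ = bm.mixture_moments(times, d, model)
        cov = model.n * bm.covariance_matrix(times, d, model) \
            + model.c ** 2 * np.eye(times.size)
        oracle = multivariate_normal(mean=mu, cov=cov).logpdf(
            data.counts_pos[:, k, :].T).sum()
        assert result.per_dose[k] == pytest.approx(oracle, rel=1e-9)


def test_endpoint_decreases_away_from_mean(case_study_model):
    times = (0.0, 10.0)
    mu, _ = bm.mixture_moments(10.0, 0.0, case_study_model)
    lls = []
    for shift in (0.0, 10.0, 30.0, 90.0):
        counts = np.full((2, 1, 1), float(case_study_model.n))
        counts[1, 0, 0] = mu + shift
        data = _dataset_from_counts(counts, times, (0.0,), case_study_model.n,
                                    mode="endpoint")
        lls.append(loglik_endpoint(case_study_model, data).loglik)
    assert np.all(np.diff(lls) < 0.0)


def test_livecell_dominates_endpoint_on_correlated_data(fig2_model):
    """At the true parameters, modeling the time correlation should win on
    most live-cell simulated datasets."""
    model = bm.MixtureModel(subpops=fig2_model.subpops, n=1000, c=5.0)
    design = bm.ExperimentDesign(times=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0),
                                 doses=(0.0,), n_replicates=10, mode="livecell")
    rng = np.random.default_rng(12)
    wins = sum(
        loglik_livecell(model, data).loglik > loglik_endpoint(model, data).loglik
        for data in (bm.simulate_dataset(model, design, rng) for _ in range(100)))
    assert wins > 50


# --------------------------------------------------------------------------
# exact path likelihood oracle (tiny instances)
# --------------------------------------------------------------------------

def _offspring_pmf(beta, nu, dt, K):
    """Distribution of one ancestor's descendant count after dt."""
    lam = beta - nu
    g = np.exp(lam * dt)
    denom = beta * g - nu
    alpha = nu * (g - 1.0) / denom
    gamma = beta * (g - 1.0) / denom
    k = np.arange(K)
    pmf = np.empty(K)
    pmf[0] = alpha
    pmf[1:] = (1.0 - alpha) * (1.0 - gamma) * gamma ** (k[1:] - 1.0)
    return pmf


def _transition_matrix(beta, nu, dt, K, nfft=8192):
    """P[i, j] = P(count j after dt | i ancestors), by FFT convolution powers."""
    pmf = _offspring_pmf(beta, nu, dt, K)
    fp = np.fft.rfft(pmf, nfft)
    rows = np.empty((K, K))
    for i in range(K):
        full = np.fft.irfft(fp ** i, nfft)
        rows[i] = np.maximum(full[:K], 0.0)
    return rows


def _exact_path_machinery(n, beta, nu, times, K):
    """Initial-count distribution and transition matrix, built once per n."""
    t1, t2 = times
    p1 = _offspring_pmf(beta, nu, t1, K)
    fp = np.fft.rfft(p1, 16384)
    dist1 = np.maximum(np.fft.irfft(fp ** n, 16384)[:K], 0.0)
    trans = _transition_matrix(beta, nu, t2 - t1, K)
    return dist1, trans


def _exact_path_loglik(x, dist1, trans, c, K):
    """Exact two-time-point path likelihood with Gaussian read noise, by
    forward summation over a truncated count space."""
    k = np.arange(K)
    phi1 = norm.pdf(x[0], loc=k, scale=c)
    phi2 = norm.pdf(x[1], loc=k, scale=c)
    inner = trans @ phi2                     # per k1
    return float(np.log(np.sum(dist1 * phi1 * inner)))


def test_gaussian_loglik_approaches_exact_path_likelihood():
    """The Gaussian live-cell log-density converges to the exact path
    log-likelihood as the initial count grows (mean |gap| shrinks)."""
    # read noise at the count-lattice scale (c = 1): narrower noise leaves a
    # local lattice factor in the exact smoothed density that no continuous
    # Gaussian can track, so convergence is only visible from c ~ 1 upward
    beta, nu, c = 0.4, 0.2, 1.0
    times = (0.5, 1.0)
    hp = bm.HillParams(0.8, 1.0, 2.0)
    gaps = []
    rng = np.random.default_rng(123)
    for n in (5, 50, 500):
        model = bm.MixtureModel([bm.Subpopulation(1.0, beta, nu, hp)], n=n, c=c)
        K = max(64, int(n * np.exp(0.2) * 3))
        dist1, trans = _exact_path_machinery(n, beta, nu, times, K)
        per_path = []
        for _ in range(40):
            path = bm.simulate_paths(model, 0.0, np.asarray(times), "livecell", rng)
            counts = np.zeros((3, 1, 1))
            counts[0, 0, 0] = n
            counts[1:, 0, 0] = path
            data = _dataset_from_counts(counts, (0.0,) + times, (0.0,), n)
            gauss = loglik_livecell(model, data).loglik
            exact = _exact_path_loglik(path, dist1, trans, c, K)
            per_path.append(abs(gauss - exact))
        gaps.append(np.mean(per_path))
    assert gaps[0] > gaps[1] > gaps[2]


def test_variance_floor_guards_degenerate_models():
    """A zero-rate, zero-noise model must not blow up the endpoint density."""
    hp = bm.HillParams(0.8, 1e6, 2.0)  # drug inert on this dose scale
    frozen = bm.MixtureModel([bm.Subpopulation(1.0, 0.0, 0.0, hp)], n=100, c=0.0)
    counts = np.full((2, 1, 1), 100.0)
    data = _dataset_from_counts(counts, (0.0, 1.0), (0.0,), 100, mode="endpoint")
    result = loglik_endpoint(frozen, data)
    assert np.isfinite(result.loglik)


def test_fast_kernels_match_reference(case_study_model, small_livecell_data):
    """The accelerated likelihood kernels used inside the optimizer agree
    with the reference implementations to near machine precision."""
    from bdmix._fast import (HAVE_NUMBA, loglik_endpoint_arrays,
                             loglik_livecell_arrays, loglik_phenopop_arrays)
    if not HAVE_NUMBA:
        # pure-python fallback computes the same formulas; still compare
        pass
    model = case_study_model
    data = small_livecell_data
    times = data.design.times_pos
    doses = np.asarray(data.design.doses)
    x = data.counts_pos
    p = np.array([s.p for s in model.subpops])
    beta = np.array([s.beta for s in model.subpops])
    nu = np.array([s.nu for s in model.subpops])
    b = np.array([s.hill.b for s in model.subpops])
    E = np.array([s.hill.E for s in model.subpops])
    m = np.array([s.hill.m for s in model.subpops])
    lc = loglik_livecell_arrays(p, beta, nu, b, E, m, model.c, float(model.n),
                                times, doses, x)
    assert lc == pytest.approx(loglik_livecell(model, data).loglik, rel=1e-9)
    ep = loglik_endpoint_arrays(p, beta, nu, b, E, m, model.c, float(model.n),
                                times, doses, x)
    assert ep == pytest.approx(loglik_endpoint(model, data).loglik, rel=1e-9)
    theta = bm.PhenoPopParams(fractions=tuple(p), alphas=tuple(beta - nu),
                              hills=tuple(s.hill for s in model.subpops),
                              sigma_H=60.0, sigma_L=8.0, T_L=18.0, D_L=0.3)
    pp = loglik_phenopop_arrays(p, beta - nu, b, E, m, 60.0, 8.0, 18.0, 0.3,
                                float(model.n), times, doses, x)
    assert pp == pytest.approx(loglik_phenopop(theta, data).loglik, rel=1e-9)
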