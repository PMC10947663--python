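"""Exact transition sampler, path simulation and synthetic screen generation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import ks_2samp

import bdmix as bm
from bdmix.simulate import _initial_subpop_counts


def gillespie(count: int, beta: float, nu: float, horizon: float, rng) -> int:
    """Event-by-event birth-death simulation (independent oracle)."""
    t, k = 0.0, count
    total_rate = beta + nu
    while k > 0:
        t += rng.exponential(1.0 / (k * total_rate)) if total_rate > 0 else np.inf
        if t >= horizon:
            break
        if rng.random() < beta / total_rate:
            k += 1
        else:
            k -= 1
    return k


def test_transition_fixed_points():
    rng = np.random.default_rng(0)
    assert bm.bd_transition_sample(123, 0.0, 0.0, 5.0, rng) == 123
    assert bm.bd_transition_sample(0, 0.9, 0.1, 1.0, rng) == 0
    arr = bm.bd_transition_sample(np.zeros(10, dtype=int), 0.5, 0.5, 1.0, rng)
    assert np.all(arr == 0)


def test_transition_rejects_invalid_inputs():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        bm.bd_transition_sample(10, -0.1, 0.2, 1.0, rng)
    with pytest.raises(ValueError):
        bm.bd_transition_sample(10, 0.1, 0.2, 0.0, rng)
    with pytest.raises(ValueError):
        bm.bd_transition_sample(-1, 0.1, 0.2, 1.0, rng)


def test_pure_death_transition_is_binomial_thinning():
    rng = np.random.default_rng(1)
    draws = bm.bd_transition_sample(np.full(50_000, 40), 0.0, 0.5, 1.0, rng)
    p_surv = np.exp(-0.5)
    assert draws.mean() == pytest.approx(40 * p_surv, rel=0.01)
    assert draws.var() == pytest.approx(40 * p_surv * (1 - p_surv), rel=0.05)


@pytest.mark.parametrize("beta,nu,dt", [
    (0.5, 0.3, 1.0),    # supercritical
    (0.3, 0.5, 1.0),    # subcritical
    (0.4, 0.4, 1.0),    # critical
    (0.8, 0.1, 0.5),
])
def test_transition_sampler_matches_gillespie(beta, nu, dt):
    """The closed-form transition draw and an event-driven oracle are
    distributionally indistinguishable (two-sample KS)."""
    rng = np.random.default_rng(99)
    n_draws, start = 4000, 25
    exact = bm.bd_transition_sample(np.full(n_draws, start), beta, nu, dt, rng)
    oracle = np.array([gillespie(start, beta, nu, dt, rng) for _ in range(n_draws)])
    assert ks_2samp(exact, oracle).pvalue > 1e-3


def test_simulate_paths_degenerate_cases():
    hp = bm.HillParams(0.8, 1.0, 2.0)
    frozen = bm.MixtureModel([bm.Subpopulation(1.0, 0.0, 0.0, hp)], n=500, c=0.0)
    rng = np.random.default_rng(2)
    path = bm.simulate_paths(frozen, 0.0, [0.0, 1.0, 2.0, 3.0], "livecell", rng)
    np.testing.assert_array_equal(path, 500.0)
    path_ep = bm.simulate_paths(frozen, 0.0, [0.0, 1.0, 2.0], "endpoint", rng)
    np.testing.assert_array_equal(path_ep, 500.0)


@pytest.mark.parametrize("mode", ["livecell", "endpoint"])
def test_simulated_mean_matches_moments(mode, fig2_model):
    rng = np.random.default_rng(31)
    times = np.array([0.0, 2.0, 4.0])
    reps = 10_000
    paths = np.array([bm.simulate_paths(fig2_model, 0.0, times, mode, rng)
                      for _ in range(200)])
    # vectorized ensemble through the dataset generator for the bulk of draws
    design = bm.ExperimentDesign(times=times, doses=[0.0], n_replicates=reps,
                                 mode=mode)
    data = bm.simulate_dataset(fig2_model, design, rng)
    mu, var = bm.mixture_moments(times[1:], 0.0, fig2_model)
    sample = data.counts[1:, 0, :]
    se = np.sqrt(var / reps)
    assert np.all(np.abs(sample.mean(axis=1) - mu) < 4.0 * se)
    assert np.all(np.abs(paths[:, 0] - fig2_model.n) < 1e-12)


def test_dataset_shape_and_known_start(case_study_model):
    design = bm.ExperimentDesign(times=(0.0, 3.0, 6.0), doses=(0.0, 0.5, 2.0),
                                 n_replicates=4, mode="endpoint")
    data = bm.simulate_dataset(case_study_model, design, np.random.default_rng(5))
    assert data.counts.shape == (3, 3, 4)
    assert np.all(data.counts[0] == case_study_model.n)


def test_autocorrelation_differs_by_mode(fig2_model):
    """Within-well residual autocorrelation: ~0 for endpoint, positive for
    live-cell imaging."""
    times = np.arange(0.0, 8.0)
    rng = np.random.default_rng(17)
    lag1 = {}
    for mode in ("livecell", "endpoint"):
        design = bm.ExperimentDesign(times=times, doses=[0.0],
                                     n_replicates=1000, mode=mode)
        data = bm.simulate_dataset(fig2_model, design, rng)
        x = data.counts[1:, 0, :]
        resid = x - x.mean(axis=1, keepdims=True)
        num = np.mean(resid[:-1] * resid[1:])
        den = np.mean(resid ** 2)
        lag1[mode] = num / den
    assert lag1["livecell"] > 0.5
    assert abs(lag1["endpoint"]) < 0.1


def test_simulation_is_reproducible(case_study_model, standard_design):
    a = bm.simulate_dataset(case_study_model, standard_design,
                            np.random.default_rng(123))
    b = bm.simulate_dataset(case_study_model, standard_design,
                            np.random.default_rng(123))
    np.testing.assert_array_equal(a.counts, b.counts)


def test_initial_count_apportionment_sums_exactly():
    rng = np.random.default_rng(8)
    for _ in range(200):
        S = rng.integers(1, 5)
        fracs = rng.dirichlet(np.ones(S))
        n = int(rng.integers(1, 10_000))
        counts = _initial_subpop_counts(n, fracs)
        assert counts.sum() == n
        assert np.all(counts >= 0)
        assert np.all(np.abs(counts - n * fracs) < 1.0)


def test_sample_parameters_respects_default_ranges():
    rng = np.random.default_rng(77)
    for _ in range(500):
        model = bm.sample_parameters(2, rng)
        s, r = model.subpops
        assert 0.3 <= s.p <= 0.5 and s.p + r.p == pytest.approx(1.0, abs=1e-12)
        for sub in model.subpops:
            assert 0.0 <= sub.beta <= 1.0
            assert max(0.0, sub.beta - 0.1) <= sub.nu <= sub.beta
            assert 0.8 <= sub.hill.b <= 0.9
            assert 1.5 <= sub.hill.m <= 5.0
        assert 0.05 <= s.hill.E <= 0.1
        assert 0.5 <= r.hill.E <= 2.5
        assert 0.0 <= model.c <= 10.0
        assert model.n == 1000


def test_sample_parameters_three_subpopulations():
    rng = np.random.default_rng(78)
    for _ in range(200):
        model = bm.sample_parameters(3, rng)
        e_vals = [s.hill.E for s in model.subpops]
        assert 0.0313 <= e_vals[0] <= 0.0625
        assert 0.25 <= e_vals[1] <= 0.375
        assert 1.25 <= e_vals[2] <= 2.5
        assert sum(s.p for s in model.subpops) == pytest.approx(1.0, abs=1e-12)


def test_design_validation():
    with pytest.raises(ValueError):
        bm.ExperimentDesign(times=(1.0, 2.0), doses=(0.0,), n_replicates=1,
                            mode="livecell")
    with pytest.raises(ValueError):
        bm.ExperimentDesign(times=(0.0, 1.0), doses=(0.5, 0.5), n_replicates=1,
                            mode="livecell")
    with pytest.raises(ValueError):
        bm.ExperimentDesign(times=(0.0, 1.0), doses=(0.5,), n_replicates=1,
                            mode="imaging")
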