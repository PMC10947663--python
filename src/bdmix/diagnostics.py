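"""Diagnostics for the Gaussian approximation of the birth-death mixture.

The live-cell likelihood replaces the exact (intractable) path law of the
total count with a multivariate Gaussian N(mu, n Sigma + c^2 I).  How good
that replacement is depends on the initial count n.  The energy distance
between two distributions F and G,

    D(F, G) = 2 E||X - Y|| - E||X - X'|| - E||Y - Y'||,

is zero iff F = G, and its empirical version over two samples is cheap to
compute in any dimension.  `gaussian_approx_scan` simulates ensembles of
live-cell count vectors at increasing n and measures their energy distance
to matched Gaussian draws; the distance shrinking with n is direct evidence
that the Gaussian likelihood is trustworthy at screening-scale seedings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import MixtureModel
from .moments import covariance_matrix, mixture_moments
from .simulate import _simulate_totals

__all__ = ["EnergyScan", "energy_distance", "gaussian_approx_scan"]

# pairwise-distance work is O((k+m)^2); larger samples are subsampled
_MAX_SAMPLE = 20_000
_CHUNK = 2048


@dataclass(frozen=True)
class EnergyScan:
    """Tidy table of empirical energy distances: columns n, dataset, D_E."""

    table: pd.DataFrame

    def medians(self) -> pd.Series:
        """Median D_E per initial count n, ordered by n."""
        return self.table.groupby("n")["D_E"].median().sort_index()


def _mean_pairwise(X: np.ndarray, Y: np.ndarray) -> float:
    """Mean Euclidean distance over all (row of X, row of Y) pairs, chunked."""
    y_sq = np.einsum("ij,ij->i", Y, Y)
    total = 0.0
    for start in range(0, X.shape[0], _CHUNK):
        chunk = X[start:start + _CHUNK]
        x_sq = np.einsum("ij,ij->i", chunk, chunk)
        d2 = x_sq[:, None] + y_sq[None, :] - 2.0 * chunk @ Y.T
        np.maximum(d2, 0.0, out=d2)
        total += np.sqrt(d2).sum()
    return total / (X.shape[0] * Y.shape[0])


def energy_distance(X, Y) -> float:
    """Empirical energy distance between two samples of equal dimension.

    X is (k, dim), Y is (m, dim) (1-d inputs are treated as univariate
    samples).  Returns 2 A - B - C where A, B, C are the mean cross-,
    within-X and within-Y pairwise Euclidean distances.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-d samples of equal dimension")
    return (2.0 * _mean_pairwise(X, Y)
            - _mean_pairwise(X, X) - _mean_pairwise(Y, Y))


def gaussian_approx_scan(model: MixtureModel, n_list, reps: int = 10_000,
                         n_datasets: int = 10, rng=None, dose: float = 0.0,
                         times=None) -> EnergyScan:
    """Energy distance between simulated screens and their Gaussian limit.

    For each initial count n in n_list and each of n_datasets repeats:
    simulate `reps` live-cell count vectors on the positive time grid
    (default 1..7), draw `reps` matched Gaussian vectors from
    N(mu, n Sigma + c^2 I), and record their empirical energy distance.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng)
    times = np.arange(1.0, 8.0) if times is None else np.asarray(times, dtype=float)
    use = min(reps, _MAX_SAMPLE)
    records = []
    for n in n_list:
        m = MixtureModel(subpops=model.subpops, n=int(n), c=model.c)
        mu, _ = mixture_moments(times, dose, m)
        cov = m.n * covariance_matrix(times, dose, m)
        if m.c > 0.0:
            cov = cov + m.c ** 2 * np.eye(times.size)
        chol = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) * np.eye(times.size))
        for ds in range(n_datasets):
            sim = _simulate_totals(m, dose, times, "livecell", reps, rng).astype(float)
            if m.c > 0.0:
                sim += rng.normal(0.0, m.c, size=sim.shape)
            gauss = mu[None, :] + rng.standard_normal((reps, times.size)) @ chol.T
            if reps > use:
                sim = sim[rng.choice(reps, use, replace=False)]
                gauss = gauss[rng.choice(reps, use, replace=False)]
            records.append({"n": int(n), "dataset": ds,
                            "D_E": energy_distance(sim, gauss)})
    return EnergyScan(table=pd.DataFrame(records))
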