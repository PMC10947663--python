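"""Exact stochastic simulation of the birth-death mixture and synthetic screens.

A linear birth-death process started from one cell has a known transition
law over an interval of length dt: with net growth lambda = beta - nu and
g = e^{lambda dt}, the lineage is extinct with probability

    alpha = nu (g - 1) / (beta g - nu),

and conditional on survival its size is geometric on {1, 2, ...} with ratio

    gamma = beta (g - 1) / (beta g - nu).

Summing over independent ancestors, the count after dt given `count`
ancestors is  survivors + NegativeBinomial(survivors, 1 - gamma)  with
survivors ~ Binomial(count, 1 - alpha).  This exact sampler makes both
acquisition modes cheap: end-point wells are a single transition from t = 0
to each observation time (independent populations per time point), and
live-cell wells are a sequence of transitions over the grid increments
(one population observed repeatedly).  Gaussian observation noise N(0, c^2)
is added independently at every positive time point; the t = 0 count is the
known seeding density n and carries no noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_model import HillParams, MixtureModel, Subpopulation, rates

__all__ = [
    "ExperimentDesign", "Dataset", "bd_transition_sample", "simulate_paths",
    "simulate_dataset", "sample_parameters", "TABLE2_RANGES", "TABLE3_RANGES",
    "LONG_TIME_GRID", "SHORT_TIME_GRID", "default_dose_grid",
]

# canonical in-silico observation grids (time unit: hours-scale, arbitrary)
LONG_TIME_GRID = tuple(float(t) for t in range(0, 37, 3))
SHORT_TIME_GRID = tuple(i / 3.0 for i in range(13))

# uniform sampling ranges for synthetic two-subpopulation screens: one
# drug-sensitive (low E) and one drug-resistant (high E) clone
TABLE2_RANGES = {
    "p": ((0.3, 0.5),),                       # sensitive fraction; resistant = complement
    "beta": (0.0, 1.0),
    "nu_gap": 0.1,                            # nu ~ U(max(0, beta - gap), beta)
    "b": (0.8, 0.9),
    "E": ((0.05, 0.1), (0.5, 2.5)),
    "m": (1.5, 5.0),
    "c": (0.0, 10.0),
    "n": 1000,
}

# three-subpopulation variant: sensitive / moderate / resistant
TABLE3_RANGES = {
    **TABLE2_RANGES,
    "p": ((0.167, 0.333), (0.167, 0.333)),
    "E": ((0.0313, 0.0625), (0.25, 0.375), (1.25, 2.5)),
}


def default_dose_grid(n_doses: int = 11) -> np.ndarray:
    """Log-spaced dose grid spanning a tenth of the lowest sensitive E to
    ten times the highest resistant E of the default sampling ranges."""
    lo = TABLE2_RANGES["E"][0][0] / 10.0
    hi = TABLE2_RANGES["E"][-1][1] * 10.0
    return np.geomspace(lo, hi, n_doses)


@dataclass(frozen=True)
class ExperimentDesign:
    """Observation grid of a drug screen.

    times        : increasing grid starting at 0 (the known seeding time).
    doses        : distinct non-negative doses.
    n_replicates : independent wells per dose.
    mode         : "endpoint" (destructive counting; each time point is an
                   independent culture) or "livecell" (the same well is
                   imaged repeatedly; counts are correlated over time).
    """

    times: tuple[float, ...]
    doses: tuple[float, ...]
    n_replicates: int
    mode: str

    def __init__(self, times, doses, n_replicates: int, mode: str):
        times = tuple(float(t) for t in times)
        doses = tuple(float(d) for d in doses)
        if len(times) < 2 or times[0] != 0.0:
            raise ValueError("times must start at 0 and contain at least one "
                             "positive observation time")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if len(set(doses)) != len(doses) or any(d < 0.0 for d in doses):
            raise ValueError("doses must be distinct and non-negative")
        if n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if mode not in ("endpoint", "livecell"):
            raise ValueError(f"mode must be 'endpoint' or 'livecell', got {mode!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "n_replicates", int(n_replicates))
        object.__setattr__(self, "mode", mode)

    @property
    def times_pos(self) -> np.ndarray:
        """Positive observation times (t = 0 excluded)."""
        return np.asarray(self.times[1:], dtype=float)


@dataclass(frozen=True)
class Dataset:
    """Observed counts on a full (time, dose, replicate) grid.

    counts has shape (N_T, N_D, N_R) aligned with design.times/doses; the
    t = 0 slice equals the known initial count n exactly.  Counts are real
    valued because observation noise is additive Gaussian.
    """

    counts: np.ndarray
    design: ExperimentDesign
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        expected = (len(self.design.times), len(self.design.doses),
                    self.design.n_replicates)
        if counts.shape != expected:
            raise ValueError(f"counts shape {counts.shape} != design grid {expected}")
        if not np.all(counts[0] == self.n):
            raise ValueError("t = 0 counts must equal the known initial count n")
        object.__setattr__(self, "counts", counts)

    @property
    def counts_pos(self) -> np.ndarray:
        """Counts at positive times, shape (N_T - 1, N_D, N_R)."""
        return self.counts[1:]


def bd_transition_sample(count, beta: float, nu: float, dt: float, rng):
    """Exact draw from the linear birth-death transition over an interval dt.

    count may be a scalar or integer array of ancestor counts (each entry an
    independent population); the return has the same shape.  The state 0 is
    absorbing.
    """
    if beta < 0.0 or nu < 0.0:
        raise ValueError("rates must be non-negative")
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    count = np.asarray(count)
    if np.any(count < 0):
        raise ValueError("count must be non-negative")
    scalar = count.ndim == 0
    count = np.atleast_1d(count).astype(np.int64)

    if beta == 0.0 and nu == 0.0:
        out = count.copy()
        return int(out[0]) if scalar else out
    if beta == 0.0:
        out = rng.binomial(count, np.exp(-nu * dt))
        return int(out[0]) if scalar else out

    lam = beta - nu
    if abs(lam * dt) < 1e-10:
        # critical case beta ~= nu
        bdt = beta * dt
        alpha = gamma = bdt / (1.0 + bdt)
    else:
        g = np.exp(lam * dt)
        denom = beta * g - nu
        alpha = nu * (g - 1.0) / denom
        gamma = beta * (g - 1.0) / denom

    survivors = rng.binomial(count, 1.0 - alpha)
    extra = np.zeros_like(survivors)
    pos = survivors > 0
    if np.any(pos):
        extra[pos] = rng.negative_binomial(survivors[pos], 1.0 - gamma)
    out = survivors + extra
    return int(out[0]) if scalar else out


def _initial_subpop_counts(n: int, fractions) -> np.ndarray:
    """Integer seeding counts per subpopulation summing to n exactly.

    round(n * p_i) with largest-remainder correction.
    """
    exact = n * np.asarray(fractions, dtype=float)
    base = np.floor(exact).astype(np.int64)
    short = n - int(base.sum())
    if short > 0:
        order = np.argsort(-(exact - base))
        base[order[:short]] += 1
    return base


def _simulate_totals(model: MixtureModel, d: float, times_pos: np.ndarray,
                     mode: str, reps: int, rng) -> np.ndarray:
    """Noise-free total counts at positive times, shape (reps, N_T)."""
    init = _initial_subpop_counts(model.n, [s.p for s in model.subpops])
    n_t = times_pos.size
    totals = np.zeros((reps, n_t), dtype=np.int64)
    for s, n0 in zip(model.subpops, init):
        death, _ = rates(d, s)
        if mode == "livecell":
            current = np.full(reps, n0, dtype=np.int64)
            prev_t = 0.0
            for j, t in enumerate(times_pos):
                current = bd_transition_sample(current, s.beta, death,
                                               t - prev_t, rng)
                totals[:, j] += current
                prev_t = float(t)
        else:
            for j, t in enumerate(times_pos):
                start = np.full(reps, n0, dtype=np.int64)
                totals[:, j] += bd_transition_sample(start, s.beta, death,
                                                     float(t), rng)
    return totals


def simulate_paths(model: MixtureModel, d: float, times, mode: str, rng) -> np.ndarray:
    """One replicate of total counts on a time grid under dose d.

    times may include a leading 0, returned as exactly n (no noise).  In
    livecell mode a single population is sampled sequentially over the grid;
    in endpoint mode each time point is an independent population simulated
    afresh from t = 0.  Gaussian N(0, c^2) noise is added per positive time.
    """
    times = np.asarray(times, dtype=float)
    has_zero = times[0] == 0.0
    times_pos = times[1:] if has_zero else times
    if np.any(times_pos <= 0.0) or np.any(np.diff(times_pos) <= 0.0):
        raise ValueError("times must be strictly increasing and non-negative")
    totals = _simulate_totals(model, d, times_pos, mode, 1, rng)[0].astype(float)
    if model.c > 0.0:
        totals = totals + rng.normal(0.0, model.c, size=totals.shape)
    if has_zero:
        return np.concatenate(([float(model.n)], totals))
    return totals


def simulate_dataset(model: MixtureModel, design: ExperimentDesign, rng) -> Dataset:
    """Simulate a full synthetic screen on the design grid.

    Doses and replicates are independent; the t = 0 slice is fixed at n.
    """
    n_t = len(design.times)
    n_d = len(design.doses)
    n_r = design.n_replicates
    counts = np.empty((n_t, n_d, n_r))
    counts[0] = float(model.n)
    times_pos = design.times_pos
    for k, d in enumerate(design.doses):
        totals = _simulate_totals(model, d, times_pos, design.mode, n_r, rng)
        noisy = totals.astype(float)
        if model.c > 0.0:
            noisy = noisy + rng.normal(0.0, model.c, size=noisy.shape)
        counts[1:, k, :] = noisy.T
    return Dataset(counts=counts, design=design, n=model.n)


def sample_parameters(S: int, rng, ranges: dict | None = None) -> MixtureModel:
    """Draw a random mixture model from uniform parameter ranges.

    Defaults: TABLE2_RANGES for S = 2, TABLE3_RANGES for S = 3.  The first
    S - 1 fractions are drawn from their ranges and the last is the
    complement; nu is drawn in (max(0, beta - nu_gap), beta); E ranges are
    per subpopulation, ordered from most to least drug sensitive.
    """
    if ranges is None:
        if S == 2:
            ranges = TABLE2_RANGES
        elif S == 3:
            ranges = TABLE3_RANGES
        else:
            raise ValueError("no default ranges for S = "
                             f"{S}; pass ranges explicitly")
    p_ranges = ranges["p"]
    e_ranges = ranges["E"]
    if len(p_ranges) != S - 1 or len(e_ranges) != S:
        raise ValueError("ranges inconsistent with S: need S-1 fraction "
                         "ranges and S dose ranges")
    fracs = [rng.uniform(lo, hi) for lo, hi in p_ranges]
    last = 1.0 - sum(fracs)
    if last < 0.0:
        raise ValueError("fraction ranges infeasible: drawn fractions exceed 1")
    fracs.append(last)
    subpops = []
    for i in range(S):
        beta = rng.uniform(*ranges["beta"])
        nu = rng.uniform(max(0.0, beta - ranges["nu_gap"]), beta)
        hp = HillParams(b=rng.uniform(*ranges["b"]),
                        E=rng.uniform(*e_ranges[i]),
                        m=rng.uniform(*ranges["m"]))
        subpops.append(Subpopulation(p=fracs[i], beta=beta, nu=nu, hill=hp))
    return MixtureModel(subpops=subpops, n=int(ranges["n"]),
                        c=rng.uniform(*ranges["c"]))
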