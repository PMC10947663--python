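"""Maximum-likelihood fitting, bootstrap confidence intervals, model selection.

Parameters are optimized on transformed scales — log for rates, half-effect
doses and noise SDs, logit for the Hill floor b, stick-breaking logits for
the initial fractions — with box bounds, via multi-start bounded L-BFGS-B
(Latin-hypercube starts).  Subpopulations are relabeled by ascending
half-effect dose E after fitting, so index 0 is always the most
drug-sensitive clone; this resolves label switching and matches the
sensitive / (moderate /) resistant naming used for synthetic screens.

Uncertainty is quantified by a nonparametric case bootstrap: whole replicate
trajectories are resampled with replacement within each dose, which
preserves the within-well time correlation that the live-cell likelihood
models.  Model size S is chosen by AIC (BIC is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from ._fast import (HAVE_NUMBA, loglik_endpoint_arrays,
                    loglik_livecell_arrays, loglik_phenopop_arrays)
from .core_model import HillParams, MixtureModel, PhenoPopParams, Subpopulation, gr50
from .likelihood import (
    loglik_endpoint,
    loglik_livecell,
    loglik_phenopop,
    n_free_params_bd,
    n_free_params_phenopop,
)
from .simulate import Dataset

__all__ = ["FitConfig", "FitResult", "BootstrapResult", "SelectionResult",
           "fit", "bootstrap_ci", "select_S", "error_metrics"]

_METHODS = ("phenopop", "endpoint", "livecell")
_PENALTY = 1e12


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the maximum-likelihood optimizer.

    n_starts          : number of Latin-hypercube multi-starts.
    maxiter           : L-BFGS-B iteration cap per start.
    refit_maxiter     : iteration cap per start for bootstrap refits.
    refit_extra_starts: fresh Latin-hypercube starts per bootstrap refit in
                        addition to the warm start at the point estimate;
                        needed because resampled likelihoods can be
                        multimodal and a warm-only refit understates the
                        bootstrap spread.
    bounds            : optional per-parameter (lo, hi) overrides on the
                        natural scale, keys among {beta, nu, b, E, m, c,
                        alpha, sigma}.
    """

    n_starts: int = 20
    maxiter: int = 500
    refit_maxiter: int = 150
    refit_extra_starts: int = 3
    bounds: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    method: str
    estimates: MixtureModel | PhenoPopParams
    loglik: float
    aic: float
    bic: float
    n_starts: int
    converged: bool
    gr50: tuple[float, ...]   # per subpopulation, sensitive first


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap confidence intervals for fractions and GR50s."""

    point: dict
    replicates: dict          # name -> array of B bootstrap estimates
    ci: dict                  # name -> (lo, hi)
    widths: dict
    B: int
    level: float
    n_failed: int


@dataclass(frozen=True)
class SelectionResult:
    """Model-size scan: one row per candidate S, lowest AIC preferred."""

    table: pd.DataFrame
    best_S: int
    fits: dict


# --------------------------------------------------------------------------
# parameter transforms
# --------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return np.log(p / (1.0 - p))


def _stick_to_fractions(q: np.ndarray, S: int) -> np.ndarray:
    """Stick-breaking: S-1 logits -> S fractions summing to 1."""
    fracs = np.empty(S)
    remaining = 1.0
    for i in range(S - 1):
        fracs[i] = _sigmoid(q[i]) * remaining
        remaining -= fracs[i]
    fracs[S - 1] = remaining
    return fracs


def _fractions_to_stick(p: np.ndarray) -> np.ndarray:
    S = p.size
    q = np.empty(S - 1)
    remaining = 1.0
    for i in range(S - 1):
        q[i] = _logit(p[i] / remaining)
        remaining -= p[i]
    return q


class _BDTransform:
    """Maps an unconstrained box vector to a MixtureModel and back.

    Layout: [q_1..q_{S-1} | per subpop: log beta, log nu, logit b, log E,
    log m | log c].
    """

    def __init__(self, S: int, n: int, doses, overrides: dict):
        self.S, self.n = S, n
        pos = np.asarray([d for d in doses if d > 0.0], dtype=float)
        d_lo = pos.min() if pos.size else 1e-3
        d_hi = pos.max() if pos.size else 1e3
        b = {
            "beta": overrides.get("beta", (1e-3, 1.0)),
            "nu": overrides.get("nu", (1e-6, 1.0)),
            "b": overrides.get("b", (2e-3, 0.998)),
            "E": overrides.get("E", (d_lo / 10.0, d_hi * 10.0)),
            "m": overrides.get("m", (0.3, 10.0)),
            "c": overrides.get("c", (1e-2, 0.3 * n)),
        }
        self.dim = (S - 1) + 5 * S + 1
        lo = np.empty(self.dim)
        hi = np.empty(self.dim)
        lo[: S - 1], hi[: S - 1] = -6.0, 6.0
        for i in range(S):
            j = (S - 1) + 5 * i
            lo[j], hi[j] = np.log(b["beta"][0]), np.log(b["beta"][1])
            lo[j + 1], hi[j + 1] = np.log(b["nu"][0]), np.log(b["nu"][1])
            lo[j + 2], hi[j + 2] = _logit(b["b"][0]), _logit(b["b"][1])
            lo[j + 3], hi[j + 3] = np.log(b["E"][0]), np.log(b["E"][1])
            lo[j + 4], hi[j + 4] = np.log(b["m"][0]), np.log(b["m"][1])
        lo[-1], hi[-1] = np.log(b["c"][0]), np.log(b["c"][1])
        self.bounds = list(zip(lo, hi))
        self.lo, self.hi = lo, hi
        self._dose_range = (d_lo, d_hi)

    def decode(self, x: np.ndarray) -> MixtureModel:
        S = self.S
        fracs = _stick_to_fractions(x[: S - 1], S)
        subpops = []
        for i in range(S):
            j = (S - 1) + 5 * i
            hp = HillParams(b=float(_sigmoid(x[j + 2])),
                            E=float(np.exp(x[j + 3])),
                            m=float(np.exp(x[j + 4])))
            subpops.append(Subpopulation(p=float(fracs[i]),
                                         beta=float(np.exp(x[j])),
                                         nu=float(np.exp(x[j + 1])),
                                         hill=hp))
        return MixtureModel(subpops=subpops, n=self.n, c=float(np.exp(x[-1])))

    def decode_arrays(self, x: np.ndarray):
        """Plain parameter arrays (p, beta, nu, b, E, m, c) without
        dataclass construction — the optimizer's hot path."""
        S = self.S
        fracs = _stick_to_fractions(x[: S - 1], S)
        base = S - 1
        block = x[base:base + 5 * S].reshape(S, 5)
        return (fracs, np.exp(block[:, 0]), np.exp(block[:, 1]),
                _sigmoid(block[:, 2]), np.exp(block[:, 3]),
                np.exp(block[:, 4]), float(np.exp(x[-1])))

    def encode(self, model: MixtureModel) -> np.ndarray:
        S = self.S
        x = np.empty(self.dim)
        x[: S - 1] = _fractions_to_stick(np.asarray([s.p for s in model.subpops]))
        for i, s in enumerate(model.subpops):
            j = (S - 1) + 5 * i
            x[j] = np.log(max(s.beta, 1e-9))
            x[j + 1] = np.log(max(s.nu, 1e-9))
            x[j + 2] = _logit(s.hill.b)
            x[j + 3] = np.log(s.hill.E)
            x[j + 4] = np.log(s.hill.m)
        x[-1] = np.log(max(model.c, 1e-9))
        return np.clip(x, self.lo + 1e-9, self.hi - 1e-9)

    def starts(self, n_starts: int, rng) -> np.ndarray:
        """Latin-hypercube starts in a practical sub-box of the bounds.

        Rates start in plausible growth ranges with nu just below beta; the
        E starts of the S subpopulations are staggered across the dose
        range on the log scale, which seeds the sensitive-to-resistant
        ordering instead of leaving it to chance.
        """
        S = self.S
        sampler = qmc.LatinHypercube(d=self.dim, seed=rng)
        u = sampler.random(n_starts)
        x = np.empty_like(u)
        x[:, : S - 1] = -1.5 + 3.0 * u[:, : S - 1]
        d_lo, d_hi = self._dose_range
        log_span = np.log(d_hi) - np.log(d_lo)
        for i in range(S):
            j = (S - 1) + 5 * i
            beta = 0.05 + 0.9 * u[:, j]
            x[:, j] = np.log(beta)
            x[:, j + 1] = np.log(beta * (0.5 + 0.49 * u[:, j + 1]))
            x[:, j + 2] = _logit(0.7 + 0.25 * u[:, j + 2])
            seg_lo = np.log(d_lo) + log_span * i / S
            x[:, j + 3] = seg_lo + log_span / S * u[:, j + 3]
            x[:, j + 4] = np.log(1.0 + 4.0 * u[:, j + 4])
        x[:, -1] = np.log(self.n * (0.005 + 0.095 * u[:, -1]))
        return np.clip(x, self.lo + 1e-9, self.hi - 1e-9)


class _PPTransform:
    """Box-vector transform for the two-level-noise growth model.

    Layout: [q_1..q_{S-1} | per subpop: alpha, logit b, log E, log m |
    log sigma_H, log sigma_L].  T_L and D_L are fixed to the grid medians.
    """

    def __init__(self, S: int, n: int, design, overrides: dict):
        self.S, self.n = S, n
        pos = np.asarray([d for d in design.doses if d > 0.0], dtype=float)
        d_lo = pos.min() if pos.size else 1e-3
        d_hi = pos.max() if pos.size else 1e3
        self.T_L = float(np.median(design.times_pos))
        self.D_L = float(np.median(design.doses))
        b = {
            "alpha": overrides.get("alpha", (-1.0, 1.0)),
            "b": overrides.get("b", (2e-3, 0.998)),
            "E": overrides.get("E", (d_lo / 10.0, d_hi * 10.0)),
            "m": overrides.get("m", (0.3, 10.0)),
            "sigma": overrides.get("sigma", (1e-2, 0.5 * n)),
        }
        self.dim = (S - 1) + 4 * S + 2
        lo = np.empty(self.dim)
        hi = np.empty(self.dim)
        lo[: S - 1], hi[: S - 1] = -6.0, 6.0
        for i in range(S):
            j = (S - 1) + 4 * i
            lo[j], hi[j] = b["alpha"]
            lo[j + 1], hi[j + 1] = _logit(b["b"][0]), _logit(b["b"][1])
            lo[j + 2], hi[j + 2] = np.log(b["E"][0]), np.log(b["E"][1])
            lo[j + 3], hi[j + 3] = np.log(b["m"][0]), np.log(b["m"][1])
        lo[-2:], hi[-2:] = np.log(b["sigma"][0]), np.log(b["sigma"][1])
        self.bounds = list(zip(lo, hi))
        self.lo, self.hi = lo, hi
        self._dose_range = (d_lo, d_hi)

    def decode(self, x: np.ndarray) -> PhenoPopParams:
        S = self.S
        fracs = _stick_to_fractions(x[: S - 1], S)
        alphas, hills = [], []
        for i in range(S):
            j = (S - 1) + 4 * i
            alphas.append(float(x[j]))
            hills.append(HillParams(b=float(_sigmoid(x[j + 1])),
                                    E=float(np.exp(x[j + 2])),
                                    m=float(np.exp(x[j + 3]))))
        return PhenoPopParams(fractions=tuple(float(f) for f in fracs),
                              alphas=tuple(alphas), hills=tuple(hills),
                              sigma_H=float(np.exp(x[-2])),
                              sigma_L=float(np.exp(x[-1])),
                              T_L=self.T_L, D_L=self.D_L)

    def decode_arrays(self, x: np.ndarray):
        S = self.S
        fracs = _stick_to_fractions(x[: S - 1], S)
        base = S - 1
        block = x[base:base + 4 * S].reshape(S, 4)
        return (fracs, block[:, 0].copy(), _sigmoid(block[:, 1]),
                np.exp(block[:, 2]), np.exp(block[:, 3]),
                float(np.exp(x[-2])), float(np.exp(x[-1])))

    def encode(self, theta: PhenoPopParams) -> np.ndarray:
        S = self.S
        x = np.empty(self.dim)
        x[: S - 1] = _fractions_to_stick(np.asarray(theta.fractions))
        for i in range(S):
            j = (S - 1) + 4 * i
            x[j] = theta.alphas[i]
            x[j + 1] = _logit(theta.hills[i].b)
            x[j + 2] = np.log(theta.hills[i].E)
            x[j + 3] = np.log(theta.hills[i].m)
        x[-2] = np.log(theta.sigma_H)
        x[-1] = np.log(theta.sigma_L)
        return np.clip(x, self.lo + 1e-9, self.hi - 1e-9)

    def starts(self, n_starts: int, rng) -> np.ndarray:
        S = self.S
        sampler = qmc.LatinHypercube(d=self.dim, seed=rng)
        u = sampler.random(n_starts)
        x = np.empty_like(u)
        x[:, : S - 1] = -1.5 + 3.0 * u[:, : S - 1]
        d_lo, d_hi = self._dose_range
        log_span = np.log(d_hi) - np.log(d_lo)
        for i in range(S):
            j = (S - 1) + 4 * i
            x[:, j] = -0.2 + 0.7 * u[:, j]
            x[:, j + 1] = _logit(0.7 + 0.25 * u[:, j + 1])
            seg_lo = np.log(d_lo) + log_span * i / S
            x[:, j + 2] = seg_lo + log_span / S * u[:, j + 2]
            x[:, j + 3] = np.log(1.0 + 4.0 * u[:, j + 3])
        x[:, -2] = np.log(self.n * (0.01 + 0.2 * u[:, -2]))
        x[:, -1] = np.log(self.n * (0.002 + 0.05 * u[:, -1]))
        return np.clip(x, self.lo + 1e-9, self.hi - 1e-9)


def _sort_by_E(result):
    """Relabel subpopulations by ascending half-effect dose (sensitive first)."""
    if isinstance(result, MixtureModel):
        order = np.argsort([s.hill.E for s in result.subpops])
        return MixtureModel(subpops=[result.subpops[i] for i in order],
                            n=result.n, c=result.c)
    order = np.argsort([h.E for h in result.hills])
    return PhenoPopParams(
        fractions=tuple(result.fractions[i] for i in order),
        alphas=tuple(result.alphas[i] for i in order),
        hills=tuple(result.hills[i] for i in order),
        sigma_H=result.sigma_H, sigma_L=result.sigma_L,
        T_L=result.T_L, D_L=result.D_L)


def _loglik_fn(method: str):
    return {"phenopop": loglik_phenopop, "endpoint": loglik_endpoint,
            "livecell": loglik_livecell}[method]


def fit(data: Dataset, S: int, method: str, config: FitConfig | None = None,
        rng=None, starts: np.ndarray | None = None,
        _maxiter: int | None = None) -> FitResult:
    """Maximum-likelihood fit of an S-subpopulation model to a screen.

    method is one of "phenopop", "endpoint", "livecell".  The best of
    config.n_starts bounded local optimizations wins (ties broken by the
    smaller parameter-vector norm); `starts` overrides the Latin-hypercube
    start set, e.g. to warm-start bootstrap refits.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if S < 1:
        raise ValueError("S must be >= 1")
    config = config or FitConfig()
    rng = np.random.default_rng(rng)
    if method == "phenopop":
        transform = _PPTransform(S, data.n, data.design, config.bounds)
    else:
        transform = _BDTransform(S, data.n, data.design.doses, config.bounds)
    loglik = _loglik_fn(method)

    if HAVE_NUMBA:
        times = np.ascontiguousarray(data.design.times_pos)
        doses = np.ascontiguousarray(data.design.doses, dtype=float)
        xobs = np.ascontiguousarray(data.counts_pos)
        n = float(data.n)

        if method == "phenopop":
            T_L, D_L = transform.T_L, transform.D_L

            def objective(x):
                fr, al, bb, ee, mm, sH, sL = transform.decode_arrays(x)
                value = loglik_phenopop_arrays(fr, al, bb, ee, mm, sH, sL,
                                               T_L, D_L, n, times, doses, xobs)
                return -value if np.isfinite(value) else _PENALTY
        else:
            kernel = (loglik_livecell_arrays if method == "livecell"
                      else loglik_endpoint_arrays)

            def objective(x):
                fr, be, nn, bb, ee, mm, cc = transform.decode_arrays(x)
                value = kernel(fr, be, nn, bb, ee, mm, cc, n, times, doses, xobs)
                return -value if np.isfinite(value) else _PENALTY
    else:
        def objective(x):
            try:
                value = loglik(transform.decode(x), data).loglik
            except (FloatingPointError, np.linalg.LinAlgError, ValueError):
                return _PENALTY
            if not np.isfinite(value):
                return _PENALTY
            return -value

    if starts is None:
        starts = transform.starts(config.n_starts, rng)
    best = None
    n_ok = 0
    for x0 in np.atleast_2d(starts):
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=transform.bounds,
                       options={"maxiter": _maxiter or config.maxiter,
                                "ftol": 1e-10})
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        n_ok += 1
        key = (res.fun, float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res.x)
    if best is None:
        raise RuntimeError(
            f"all {len(np.atleast_2d(starts))} optimization starts failed for "
            f"method={method}, S={S}")

    estimates = _sort_by_E(transform.decode(best[1]))
    ll = loglik(estimates, data).loglik
    k = n_free_params_phenopop(S) if method == "phenopop" else n_free_params_bd(S)
    n_obs = data.counts_pos.size
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * np.log(n_obs)
    hills = (estimates.hills if isinstance(estimates, PhenoPopParams)
             else tuple(s.hill for s in estimates.subpops))
    return FitResult(method=method, estimates=estimates, loglik=float(ll),
                     aic=float(aic), bic=float(bic),
                     n_starts=len(np.atleast_2d(starts)), converged=n_ok > 0,
                     gr50=tuple(gr50(h) for h in hills))


def _target_values(result: FitResult) -> dict:
    """Fractions and GR50s keyed by sensitivity rank (index 0 = sensitive)."""
    est = result.estimates
    fracs = (est.fractions if isinstance(est, PhenoPopParams)
             else tuple(s.p for s in est.subpops))
    out = {}
    for i, (p, g) in enumerate(zip(fracs, result.gr50)):
        out[f"p_{i}"] = float(p)
        out[f"gr50_{i}"] = float(g)
    return out


def _resample_dataset(data: Dataset, rng) -> Dataset:
    """Case bootstrap: resample whole replicate trajectories within each dose."""
    counts = np.empty_like(data.counts)
    counts[0] = data.counts[0]
    n_r = data.design.n_replicates
    for k in range(len(data.design.doses)):
        idx = rng.integers(0, n_r, size=n_r)
        counts[1:, k, :] = data.counts[1:, k, idx]
    return Dataset(counts=counts, design=data.design, n=data.n)


def bootstrap_ci(data: Dataset, S: int, method: str, B: int = 100,
                 level: float = 0.95, config: FitConfig | None = None,
                 rng=None) -> BootstrapResult:
    """Percentile bootstrap CIs for the initial fractions and GR50 doses.

    B case-bootstrap resamples (replicates resampled with replacement within
    each dose, keeping each well's full time vector intact) are refit with a
    single optimization start warm-started at the point estimate.  Fails if
    more than 20% of the refits error out.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or FitConfig()
    rng = np.random.default_rng(rng)
    point_fit = fit(data, S, method, config=config, rng=rng)
    if method == "phenopop":
        transform = _PPTransform(S, data.n, data.design, config.bounds)
    else:
        transform = _BDTransform(S, data.n, data.design.doses, config.bounds)
    warm = transform.encode(point_fit.estimates)

    reps: dict[str, list] = {k: [] for k in _target_values(point_fit)}
    n_failed = 0
    for _ in range(B):
        resampled = _resample_dataset(data, rng)
        # warm start plus fresh starts: resampled likelihoods can be
        # multimodal, and a warm-only refit understates the spread
        if config.refit_extra_starts > 0:
            starts = np.vstack([warm[None, :],
                                transform.starts(config.refit_extra_starts, rng)])
        else:
            starts = warm[None, :]
        try:
            refit = fit(resampled, S, method, config=config, rng=rng,
                        starts=starts, _maxiter=config.refit_maxiter)
        except RuntimeError:
            n_failed += 1
            continue
        for k, v in _target_values(refit).items():
            reps[k].append(v)
    if n_failed > 0.2 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap refits failed")

    alpha = (1.0 - level) / 2.0
    replicates = {k: np.asarray(v) for k, v in reps.items()}
    ci = {k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha)))
          for k, v in replicates.items()}
    widths = {k: hi - lo for k, (lo, hi) in ci.items()}
    return BootstrapResult(point=_target_values(point_fit),
                           replicates=replicates, ci=ci, widths=widths,
                           B=B, level=level, n_failed=n_failed)


def select_S(data: Dataset, method: str, S_candidates,
             config: FitConfig | None = None, rng=None) -> SelectionResult:
    """Fit each candidate number of subpopulations and rank by AIC."""
    S_candidates = list(S_candidates)
    if not S_candidates or min(S_candidates) < 1:
        raise ValueError("S candidates must be >= 1")
    rng = np.random.default_rng(rng)
    rows = []
    fits = {}
    for S in S_candidates:
        result = fit(data, S, method, config=config, rng=rng)
        fits[S] = result
        k = (n_free_params_phenopop(S) if method == "phenopop"
             else n_free_params_bd(S))
        rows.append({"S": S, "loglik": result.loglik, "n_params": k,
                     "AIC": result.aic, "BIC": result.bic})
    table = pd.DataFrame(rows)
    best_S = int(table.loc[table["AIC"].idxmin(), "S"])
    return SelectionResult(table=table, best_S=best_S, fits=fits)


def error_metrics(estimate: float, truth: float) -> dict:
    """Point-estimation error on the log and relative scales.

    abs_log_ratio  = |log(truth / estimate)|  (symmetric on the log scale,
                     suited to dose-like quantities);
    relative_error = |truth - estimate| / |truth|.
    """
    if truth <= 0.0:
        raise ValueError("truth must be positive")
    if estimate <= 0.0:
        raise ValueError("estimate must be positive for the log-ratio metric")
    return {"abs_log_ratio": abs(np.log(truth / estimate)),
            "relative_error": abs(truth - estimate) / abs(truth)}
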