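"""Dose-response primitives: Hill curve, dose-dependent rates, GR50.

Each subpopulation of tumor cells is a linear birth-death process whose
death rate increases with drug dose d through a Hill curve

    H(d; b, E, m) = b + (1 - b) / (1 + (d/E)^m),

with b in (0, 1) the residual fraction at saturating dose, E > 0 the
half-effect dose and m > 0 the steepness.  H(0) = 1 and H(d) -> b as
d -> infinity, so -log b is the maximal drug effect on the death rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HillParams", "Subpopulation", "MixtureModel", "PhenoPopParams",
           "hill", "rates", "gr50"]


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response triple (b, E, m).

    b : residual effect floor, dimensionless, 0 < b < 1.
    E : half-effect dose, in the units of the applied doses, E > 0.
    m : steepness of the dose-response curve, m > 0.
    """

    b: float
    E: float
    m: float

    def __post_init__(self) -> None:
        if not (0.0 < self.b < 1.0):
            raise ValueError(f"b must be in (0, 1), got {self.b}")
        if self.E <= 0.0:
            raise ValueError(f"E must be positive, got {self.E}")
        if self.m <= 0.0:
            raise ValueError(f"m must be positive, got {self.m}")


@dataclass(frozen=True)
class Subpopulation:
    """One tumor subpopulation: initial fraction, rates and dose response.

    p    : initial fraction of the total population, in [0, 1].
    beta : cell division rate per unit time, >= 0.
    nu   : baseline (drug-free) death rate per unit time, >= 0.
    hill : Hill dose-response parameters of the drug-induced death rate.
    """

    p: float
    beta: float
    nu: float
    hill: HillParams

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.nu < 0.0:
            raise ValueError(f"nu must be >= 0, got {self.nu}")


@dataclass(frozen=True)
class MixtureModel:
    """Mixture of S independent birth-death subpopulations.

    subpops : ordered subpopulations; initial fractions must sum to 1.
    n       : known initial total cell count (integer, >= 1).
    c       : standard deviation of additive Gaussian observation noise, cells.
    """

    subpops: tuple[Subpopulation, ...]
    n: int
    c: float

    def __init__(self, subpops, n: int, c: float):
        subpops = tuple(subpops)
        if len(subpops) < 1:
            raise ValueError("at least one subpopulation is required")
        total = sum(s.p for s in subpops)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"initial fractions must sum to 1, got {total!r}")
        if n < 1 or int(n) != n:
            raise ValueError(f"n must be a positive integer, got {n}")
        if c < 0.0:
            raise ValueError(f"c must be >= 0, got {c}")
        object.__setattr__(self, "subpops", subpops)
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "c", float(c))

    @property
    def S(self) -> int:
        return len(self.subpops)


@dataclass(frozen=True)
class PhenoPopParams:
    """Parameters of the deterministic-growth predecessor model.

    Each subpopulation grows deterministically at exponential rate
    alpha_i + log H_i(d); observations carry additive Gaussian noise with
    one of two variance levels: sigma_H^2 at late times and low doses
    (t >= T_L and d <= D_L), sigma_L^2 otherwise.
    """

    fractions: tuple[float, ...]        # p_i, sum to 1
    alphas: tuple[float, ...]           # net growth rates, any sign
    hills: tuple[HillParams, ...]
    sigma_H: float
    sigma_L: float
    T_L: float
    D_L: float

    def __post_init__(self) -> None:
        if not (len(self.fractions) == len(self.alphas) == len(self.hills)):
            raise ValueError("fractions, alphas and hills must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("initial fractions must sum to 1")
        if self.sigma_H <= 0.0 or self.sigma_L <= 0.0:
            raise ValueError("noise SDs must be positive")

    @property
    def S(self) -> int:
        return len(self.fractions)


def hill(d, hp: HillParams):
    """Evaluate the Hill dose-response curve H(d; b, E, m).

    Returns b + (1-b)/(1 + (d/E)^m); strictly decreasing in d, with
    H(0) = 1 exactly and H(d) -> b as d -> infinity.  Accepts scalar or
    array doses; negative doses raise ValueError.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("dose must be non-negative")
    # d = 0 is returned as exactly 1 so the zero-dose branch carries no
    # m-dependent floating error from evaluating 0^m.
    with np.errstate(over="ignore"):
        ratio = (d / hp.E) ** hp.m
    out = np.where(d == 0.0, 1.0, hp.b + (1.0 - hp.b) / (1.0 + ratio))
    if out.ndim == 0:
        return float(out)
    return out


def rates(d, s: Subpopulation):
    """Dose-dependent death rate and net growth rate of a subpopulation.

    death rate  nu(d)    = nu - log H(d)      (cytotoxic action: the drug
                                               raises the death rate)
    net growth  lambda(d) = beta - nu(d) = (beta - nu) + log H(d)

    The two outputs always satisfy death + net_growth = beta.
    """
    h = hill(d, s.hill)
    log_h = np.log(h)
    death = s.nu - log_h
    net = s.beta - death
    return death, net


def gr50(hp: HillParams) -> float:
    """Dose at which the drug has half its maximal effect on the death rate.

    The drug's effect on the death rate at dose d is -log H(d), with
    supremum -log b as d -> infinity.  GR50 solves -log H(d) = -log(b)/2,
    i.e. H(d) = sqrt(b), which in closed form is

        GR50 = E * b^(-1/(2m))  > E.
    """
    return hp.E * hp.b ** (-1.0 / (2.0 * hp.m))
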