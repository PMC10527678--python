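"""Latent physiological state variables derived from off-gas measurements.

In aerobic fed-batch cultivations of *E. coli* the oxygen uptake rate (OUR)
tracks biomass formation: growth consumes oxygen in proportion to the newly
formed biomass (yield factor ``alpha``), and once the culture has accumulated
enough biomass-time, a maintenance demand proportional to the standing biomass
(coefficient ``beta``) adds to the oxygen draw.  Inverting that relation,

    OUR(t) = alpha * dx/dt + beta * (x - X_cX)        (maintenance phase)

gives a *latent* biomass concentration trajectory x(t) from the measured OUR
alone, without any at-line sampling.  From x(t) three further physiological
descriptors follow: the specific growth rate mu = (dx/dt)/x, the average age
of the biomass population (each increment of biomass is a cohort born at its
time of appearance), and the cumulative cell age, the biomass-weighted
integral of those cohort ages.

These four trajectories are the "latent variables" that the soft sensor uses
alongside the raw measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import DomainError, InvalidInputError, ParameterError

__all__ = [
    "CultivationRecord",
    "StrainParams",
    "LatentStates",
    "latent_biomass",
    "specific_growth_rate",
    "average_age",
    "cumulative_age",
    "derive_all",
]

ArrayLike = Union[np.ndarray, list, tuple, float]


def _as1d(x, name: str, n: Optional[int] = None) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if n is not None and arr.size != n:
        raise InvalidInputError(f"{name} has length {arr.size}, expected {n}")
    return arr


@dataclass
class CultivationRecord:
    """One cultivation's measured time series plus metadata.

    All per-instant series are aligned on ``times`` (hours since inoculation).
    OUR and CPR are volumetric rates in g L^-1 h^-1; ``broth_weight`` is in kg;
    feed profiles are mass rates in g h^-1.
    """

    experiment_id: str
    times: np.ndarray
    our: np.ndarray
    cpr: np.ndarray
    broth_weight: np.ndarray
    feed_glucose: np.ndarray
    x0: float
    s0: float
    feed_isoleucine: Optional[np.ndarray] = None
    induction_time: Optional[float] = None

    def __post_init__(self):
        self.times = _as1d(self.times, "times")
        n = self.times.size
        if n == 0:
            raise InvalidInputError("record must contain at least one instant")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        for name in ("our", "cpr", "broth_weight", "feed_glucose"):
            setattr(self, name, _as1d(getattr(self, name), name, n))
        if self.feed_isoleucine is not None:
            self.feed_isoleucine = _as1d(self.feed_isoleucine, "feed_isoleucine", n)
        if np.any(self.our < 0):
            raise InvalidInputError("our must be non-negative")
        if np.any(self.broth_weight < 0):
            raise InvalidInputError("broth_weight must be non-negative")
        if not self.x0 > 0:
            raise InvalidInputError("x0 must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class StrainParams:
    """Strain-specific nuisance parameters of the OUR -> biomass model.

    ``alpha`` [g O2 / g X] and ``beta`` [g O2 g X^-1 h^-1] may be constants or
    per-instant series; ``k_cX`` [g h / L] is the cumulative biomass-time
    threshold after which the maintenance term enters; ``X_cX`` [g/L] is the
    maintenance reference biomass level (0 disables it).
    """

    alpha: ArrayLike = 1.0
    beta: ArrayLike = 0.0
    k_cX: float = 0.0
    X_cX: float = 0.0

    def resolve(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast alpha/beta to per-instant arrays of length ``n``."""
        alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), (n,)).copy() \
            if np.ndim(self.alpha) == 0 else _as1d(self.alpha, "alpha", n)
        beta = np.broadcast_to(np.asarray(self.beta, dtype=float), (n,)).copy() \
            if np.ndim(self.beta) == 0 else _as1d(self.beta, "beta", n)
        if np.any(alpha <= 0):
            raise ParameterError("alpha must be strictly positive everywhere")
        if np.any(beta < 0):
            raise ParameterError("beta must be non-negative")
        if self.k_cX < 0:
            raise ParameterError("k_cX must be non-negative")
        return alpha, beta


@dataclass
class LatentStates:
    """Bundle of the derived physiological trajectories."""

    times: np.ndarray
    biomass: np.ndarray          # x(t) [g/L]
    mu: np.ndarray               # specific growth rate [1/h]
    age: np.ndarray              # population-average cell age [h]
    cage: np.ndarray             # cumulative cell age [g h / L]
    cum_biomass_time: np.ndarray = field(default=None)  # sum X dt [g h / L]


def latent_biomass(record: CultivationRecord, params: StrainParams) -> np.ndarray:
    """Reconstruct the latent biomass concentration x(t) from OUR.

    Discretizes ``alpha * dx/dt + beta * (x - X_cX) = OUR`` with an
    integrating factor.  The maintenance term is inactive (beta treated as 0)
    while the cumulative biomass-time ``sum_{j<=i-1} x_j dt_j`` stays at or
    below ``k_cX``; once crossed it stays active, and the trajectory is
    continuous at the switch.  With beta = 0 the scheme reduces exactly to
    ``x0 + cumsum(OUR * dt / alpha)``.
    """
    n = len(record)
    alpha, beta = params.resolve(n)
    t = record.times
    our = record.our

    x = np.empty(n)
    x[0] = record.x0
    cum = 0.0          # cumulative biomass-time up to the previous instant
    log_E = 0.0        # log of the integrating factor exp(sum beta/alpha dt)
    numer = record.x0  # accumulates x0 + sum (OUR + beta*X_cX)/alpha * E * dt
    maintenance_on = False
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        if i >= 2:
            cum += x[i - 1] * (t[i - 1] - t[i - 2])
        if not maintenance_on and cum > params.k_cX:
            maintenance_on = True
        b = beta[i] if maintenance_on else 0.0
        log_E += b / alpha[i] * dt
        E = np.exp(log_E)
        numer += (our[i] + b * params.X_cX) / alpha[i] * E * dt
        x[i] = numer / E
    return x


def specific_growth_rate(biomass: ArrayLike, times: ArrayLike) -> np.ndarray:
    """mu(t) = (dx/dt) / x via second-order central differences.

    Interior points use the three-point central scheme on the (possibly
    non-uniform) grid; the end points use one-sided differences.  A length-1
    series has mu = 0 by convention.
    """
    x = _as1d(biomass, "biomass")
    t = _as1d(times, "times", x.size)
    if np.any(x <= 0):
        raise DomainError("biomass must be strictly positive to evaluate mu")
    if x.size == 1:
        return np.zeros(1)
    return np.gradient(x, t) / x


def _cohort_weighted_ages(biomass: np.ndarray, times: np.ndarray) -> np.ndarray:
    """sum_j (t_i - t_j) * dX_j with dX_0 := x(t_0), via prefix sums."""
    x = _as1d(biomass, "biomass")
    t = _as1d(times, "times", x.size)
    dX = np.empty_like(x)
    dX[0] = x[0]                      # the inoculum cohort, born at t0
    dX[1:] = np.diff(x)
    # sum_j (t_i - t_j) dX_j = t_i * sum_j dX_j - sum_j t_j dX_j = t_i*x_i - M_i
    return t * np.cumsum(dX) - np.cumsum(t * dX)


def cumulative_age(biomass: ArrayLike, times: ArrayLike) -> np.ndarray:
    """Cumulative cell age cAge_i = sum_j (t_i - t_j) dX(t_j) [g h / L]."""
    return _cohort_weighted_ages(np.asarray(biomass, dtype=float).ravel(),
                                 np.asarray(times, dtype=float).ravel())


def average_age(biomass: ArrayLike, times: ArrayLike) -> np.ndarray:
    """Population-average cell age Age_i = cAge_i / x_i [h].

    Biomass increments are treated as cohorts born at their instant of
    appearance; negative increments (decline) enter the sums signed.
    """
    x = _as1d(biomass, "biomass")
    if np.any(x <= 0):
        raise DomainError("biomass must be strictly positive to evaluate age")
    t = _as1d(times, "times", x.size)
    if x.size == 1:
        return np.zeros(1)
    return _cohort_weighted_ages(x, t) / x


def derive_all(record: CultivationRecord, params: StrainParams) -> LatentStates:
    """Derive every latent trajectory for a cultivation record."""
    x = latent_biomass(record, params)
    t = record.times
    if len(record) == 1:
        mu = np.zeros(1)
        age = np.zeros(1)
    else:
        mu = specific_growth_rate(x, t)
        age = average_age(x, t)
    cage = cumulative_age(x, t)
    # cumulative biomass-time sum_{j<=i} x_j dt_j with dt_j = t_j - t_{j-1}
    if len(record) > 1:
        cum_xt = np.concatenate(([0.0], np.cumsum(x[1:] * np.diff(t))))
    else:
        cum_xt = np.zeros(1)
    return LatentStates(times=t.copy(), biomass=x, mu=mu, age=age, cage=cage,
                        cum_biomass_time=cum_xt)
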