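"""Closed-form fitness landscapes over TF binding energy.

Two families are supported.  The Fermi-Dirac landscape

    F(E) = f0 + (1 - f0) * p(E),      p(E) = 1 / (1 + exp(beta * (E - mu)))

interpolates between fitness 1 for an always-bound site and f0 for a
never-bound one, weighting by the thermodynamic occupancy p.  beta and mu
are *effective* parameters that need not equal their physical counterparts.
The exponential landscape is parameterized by the single identifiable
product ``rate = nu * beta_s``, with F(E)^nu = exp(-rate * E).

The module also provides the local selection strength |s*| = |d ln F / dE|,
its sensitivity to beta, and the stationarity boundaries of that
sensitivity in the (beta, E - mu) plane, which for f0 = 0 reduce to the
Lambert-W curve beta * (E - mu) = -(1 + W(1/e)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, lambertw


@dataclass
class FermiDiracParams:
    """Effective Fermi-Dirac landscape parameters.

    f0 : fitness of a never-bound site, in [0, 1].
    beta : effective inverse temperature, (kcal/mol)^-1, > 0.
    mu : effective chemical potential (energy of half occupancy), kcal/mol.
    nu : scaling effective population size (exponent in P ~ pi0 F^nu), >= 0.
    """

    f0: float
    beta: float
    mu: float
    nu: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must be in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")

    @property
    def gamma(self) -> float:
        """Identifiable selection-strength combination nu * (1 - f0)."""
        return self.nu * (1.0 - self.f0)


@dataclass
class ExponentialParams:
    """Exponential landscape; only the product nu * beta_s is identifiable."""

    rate: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")


def occupancy(E, beta: float, mu: float):
    """Fermi-Dirac binding probability p = 1/(1 + exp(beta (E - mu)))."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return expit(-beta * (np.asarray(E, dtype=float) - mu))


def fd_fitness(E, params: FermiDiracParams):
    """F = f0 + (1 - f0) p(E), bounded in [f0, 1]."""
    return params.f0 + (1.0 - params.f0) * occupancy(E, params.beta, params.mu)


def log_fd_fitness(E, f0: float, beta: float, mu: float):
    """Numerically stable ln F for the Fermi-Dirac landscape."""
    x = beta * (np.asarray(E, dtype=float) - mu)
    lnp = -np.logaddexp(0.0, x)
    if f0 == 0.0:
        return lnp
    if f0 >= 1.0:
        return np.zeros_like(lnp)
    return np.logaddexp(np.log(f0), np.log1p(-f0) + lnp)


def exp_fitness(E, params: ExponentialParams):
    """Selection weight F^nu = exp(-rate * E) of the exponential landscape."""
    return np.exp(-params.rate * np.asarray(E, dtype=float))


def local_selection_strength(E, params: FermiDiracParams):
    """|s*| = |d ln F / dE| = beta (1 - f0) p (1 - p) / F."""
    p = occupancy(E, params.beta, params.mu)
    F = params.f0 + (1.0 - params.f0) * p
    return params.beta * (1.0 - params.f0) * p * (1.0 - p) / F


def selection_beta_sensitivity(E, params: FermiDiracParams):
    """Analytic d|s*|/dbeta at fixed (E - mu) and f0.

    With x = beta (E - mu), |s*| = beta * A(x) and
    d|s*|/dbeta = A + x A'(x)
               = (1-f0) p (1-p) / F^2 * [F + x (-(1-2p) F + (1-f0) p (1-p))].
    """
    f0, beta, mu = params.f0, params.beta, params.mu
    x = beta * (np.asarray(E, dtype=float) - mu)
    p = expit(-x)
    F = f0 + (1.0 - f0) * p
    pq = p * (1.0 - p)
    bracket = F + x * (-(1.0 - 2.0 * p) * F + (1.0 - f0) * pq)
    return (1.0 - f0) * pq / F**2 * bracket


def _stationarity(x: float, f0: float) -> float:
    """Bracketed factor of d|s*|/dbeta as a function of x = beta (E - mu)."""
    p = expit(-x)
    F = f0 + (1.0 - f0) * p
    pq = p * (1.0 - p)
    return F + x * (-(1.0 - 2.0 * p) * F + (1.0 - f0) * pq)


def beta_sensitivity_roots(f0: float, x_range: tuple = (-80.0, 80.0), n_scan: int = 4000):
    """Roots x* of d|s*|/dbeta = 0 (in x = beta (E - mu)), sorted.

    For f0 = 0 the single root is -(1 + W(1/e)) ~ -1.2785; for 0 < f0 < 1
    there are two roots bracketing the sign change; f0 = 1 has none.
    """
    if f0 >= 1.0:
        return []
    xs = np.linspace(x_range[0], x_range[1], n_scan)
    vals = np.array([_stationarity(x, f0) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            roots.append(float(xs[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(float(brentq(_stationarity, xs[i], xs[i + 1], args=(f0,), xtol=1e-13)))
    return sorted(roots)


def lambert_boundary_x() -> float:
    """x = -(1 + W(1/e)), the f0 = 0 stationarity point of |s*| in beta."""
    return -(1.0 + float(lambertw(np.exp(-1.0)).real))


def regime_boundaries(f0: float, betas=None):
    """Boundary curves of sign(d|s*|/dbeta) in the (beta, E - mu) plane.

    The stationarity condition depends on beta and E - mu only through
    x = beta (E - mu), so each boundary is a hyperbola E - mu = x*/beta.
    Returns a list of curves, one per root x*; each curve is the array of
    E - mu values over ``betas`` (default: 50 log-spaced values in
    [0.1, 10]).  For f0 = 1 the landscape is flat and the list is empty.
    """
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must be in [0, 1]")
    if betas is None:
        betas = np.logspace(-1, 1, 50)
    betas = np.asarray(betas, dtype=float)
    return [(betas, x_star / betas) for x_star in beta_sensitivity_roots(f0)]


def classify_regime(
    params: FermiDiracParams,
    site_energies,
    threshold: float = 2.0,
    bulk: float = 0.8,
) -> str:
    """Place a site collection on the Fermi-Dirac landscape.

    'exponential_tail' if the central ``bulk`` fraction of beta (E - mu)
    exceeds +threshold, 'plateau' if below -threshold, else 'threshold'.
    The cutoffs are conventions, not fitted quantities.
    """
    E = np.asarray(site_energies, dtype=float)
    if E.size == 0:
        raise ValueError("no site energies")
    x = params.beta * (E - params.mu)
    tail = (1.0 - bulk) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    if lo > threshold:
        return "exponential_tail"
    if hi < -threshold:
        return "plateau"
    return "threshold"
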