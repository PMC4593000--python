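"""Generalized logistic growth model and QFA fitness measures.

Colony density on a spotted agar culture is modelled by the generalized
logistic ODE

    dx/dt = r * x * (1 - (x/K)**nu)

with analytical solution

    x(t) = K / (1 + ((K/x0)**nu - 1) * exp(-r*nu*t))**(1/nu)

where ``x0`` is the (shared) cell density at inoculation, ``r`` a growth-rate
parameter (per day), ``K`` the carrying capacity and ``nu`` a dimensionless
shape parameter controlling the symmetry of the curve (``nu=1`` recovers the
ordinary logistic).

Fitness of a culture is summarised by

* MDR, the maximum doubling rate: the reciprocal of the time for the fitted
  curve to first reach ``2*x0`` (doublings/day);
* MDP, the maximum doubling potential: ``log2(K/x0)`` (doublings);
* fitness = MDR * MDP (doublings^2/day), the scalar used for interaction
  inference downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GrowthParams",
    "GrowthCurve",
    "FitResult",
    "FitnessRecord",
    "FitConfig",
    "density_at",
    "mdp",
    "mdr",
    "fitness_of",
    "fit_curve",
    "choose_x0",
]

_LN2 = math.log(2.0)


class ParameterDomainError(ValueError):
    """Growth parameters outside their biological domain."""


@dataclass(frozen=True)
class GrowthParams:
    """Generalized logistic parameter set for one culture.

    Invariants: ``x0 > 0``, ``K >= x0``, ``r >= 0``, ``nu > 0``.
    """

    x0: float
    r: float
    K: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.x0 > 0):
            raise ParameterDomainError(f"x0 must be positive, got {self.x0}")
        if not (self.K >= self.x0):
            raise ParameterDomainError(f"K ({self.K}) must be >= x0 ({self.x0})")
        if not (self.r >= 0):
            raise ParameterDomainError(f"r must be non-negative, got {self.r}")
        if not (self.nu > 0):
            raise ParameterDomainError(f"nu must be positive, got {self.nu}")


@dataclass(frozen=True)
class GrowthCurve:
    """Observed (time, density) series for one spotted culture.

    ``observations`` is a sequence of (time since inoculation in days,
    density estimate) pairs, strictly increasing in time.
    """

    culture_id: str
    plate: str
    row: int
    col: int
    gene: str
    background: str
    temperature: float
    observations: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise ValueError(f"{self.culture_id}: curve needs >= 1 observation")
        times = [t for t, _ in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"{self.culture_id}: times must be strictly increasing")
        if any(x < 0 for _, x in self.observations):
            raise ValueError(f"{self.culture_id}: densities must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.observations], dtype=float)

    @property
    def densities(self) -> np.ndarray:
        return np.asarray([x for _, x in self.observations], dtype=float)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one growth curve."""

    params: GrowthParams
    rss: float
    n_points: int
    converged: bool
    never_doubles: bool = False


@dataclass(frozen=True)
class FitnessRecord:
    """MDR, MDP and their product for one culture."""

    culture_id: str
    mdr: float
    mdp: float
    fitness: float


@dataclass(frozen=True)
class FitConfig:
    """Bounds and multi-start grid for the bounded least-squares fit.

    The fit is deterministic: initial values are taken from a fixed
    3 x 3 x 3 grid over (r, K, nu); the grid points are ranked by their
    initial residual sum of squares and the best ``n_refine`` are polished
    with bounded least squares.
    """

    r_bounds: tuple[float, float] = (1e-6, 50.0)
    nu_bounds: tuple[float, float] = (0.1, 10.0)
    k_upper_factor: float = 10.0  # K upper bound = factor * max observed density
    r_grid: tuple[float, ...] = (0.5, 2.5, 10.0)
    k_grid_factors: tuple[float, ...] = (1.0, 1.5, 3.0)  # times max observed density
    nu_grid: tuple[float, ...] = (0.3, 1.0, 3.0)
    n_refine: int = 5
    max_nfev: int = 200


def density_at(params: GrowthParams, t) -> np.ndarray | float:
    """Analytical solution x(t) of the generalized logistic model.

    Vectorised over ``t`` (days). Monotone non-decreasing, x(0)=x0 and
    x(t) -> K as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    x0, r, K, nu = params.x0, params.r, params.K, params.nu
    # (K/x0)**nu - 1 via expm1 for accuracy when K ~ x0
    a = np.expm1(nu * math.log(K / x0))
    x = K * (1.0 + a * np.exp(-r * nu * t)) ** (-1.0 / nu)
    return x if x.ndim else float(x)


def mdp(params: GrowthParams) -> float:
    """Maximum doubling potential, log2(K/x0): doublings from inoculum to K."""
    return math.log(params.K / params.x0) / _LN2


def mdr(params: GrowthParams) -> float:
    """Maximum doubling rate, 1 / (time for x(t) to first reach 2*x0).

    Closed form MDR = r*nu / ln[((K/x0)**nu - 1) / ((K/(2*x0))**nu - 1)].
    A culture whose carrying capacity never reaches twice the inoculum
    (K <= 2*x0) never doubles: MDR = 0. In the dilute-inoculum limit
    x0/K -> 0, MDR -> r/ln 2.
    """
    x0, r, K, nu = params.x0, params.r, params.K, params.nu
    if r == 0.0 or K <= 2.0 * x0:
        return 0.0
    num = math.expm1(nu * math.log(K / x0))
    den = math.expm1(nu * math.log(K / (2.0 * x0)))
    return r * nu / math.log(num / den)


def never_doubles(params: GrowthParams) -> bool:
    """True when the fitted culture can never reach twice the inoculum density."""
    return params.r == 0.0 or params.K <= 2.0 * params.x0


def fitness_of(fit: FitResult, culture_id: str = "") -> FitnessRecord:
    """Derive MDR, MDP and fitness = MDR * MDP from a fitted curve."""
    p = fit.params
    m_rate = mdr(p)
    m_pot = mdp(p)
    return FitnessRecord(
        culture_id=culture_id,
        mdr=m_rate,
        mdp=m_pot,
        fitness=m_rate * m_pot,
    )


def choose_x0(first_point_densities: Sequence[float], quantile: float = 0.05) -> float:
    """Shared inoculum density for an experiment.

    x0 is held constant for all spots on all plates; the default policy takes
    the 5th percentile of first-timepoint densities across all curves, a
    robust floor under multiplicative measurement noise.
    """
    d = np.asarray(first_point_densities, dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    if d.size == 0:
        raise ValueError("no positive first-timepoint densities to choose x0 from")
    return float(np.quantile(d, quantile))


def _residuals(theta: np.ndarray, t: np.ndarray, x: np.ndarray, x0: float) -> np.ndarray:
    r, K, nu = theta
    a = np.expm1(nu * np.log(K / x0))
    model = K * (1.0 + a * np.exp(-r * nu * t)) ** (-1.0 / nu)
    return model - x


def fit_curve(curve: GrowthCurve, x0: float, cfg: FitConfig | None = None) -> FitResult:
    """Bounded least-squares fit of (r, K, nu) with x0 held fixed.

    Residuals are on the linear density scale. Returns a dead-culture result
    (K=x0, r=0) when the culture never exceeds the inoculum density, and a
    degenerate non-converged fallback when there are fewer than 4 points.
    """
    if cfg is None:
        cfg = FitConfig()
    if not x0 > 0:
        raise ParameterDomainError(f"x0 must be positive, got {x0}")

    t = curve.times
    x = curve.densities
    n = t.size

    dead = GrowthParams(x0=x0, r=0.0, K=x0, nu=1.0)
    max_obs = float(x.max()) if n else 0.0

    if max_obs <= x0:
        # culture never grew above inoculum: biologically dead/failed spot
        rss = float(np.sum((x - x0) ** 2))
        return FitResult(params=dead, rss=rss, n_points=n, converged=True,
                         never_doubles=True)

    if n < 4:
        rss = float(np.sum((x - x0) ** 2))
        return FitResult(params=dead, rss=rss, n_points=n, converged=False,
                         never_doubles=True)

    k_hi = max(cfg.k_upper_factor * max_obs, x0 * (1.0 + 1e-9))
    lo = np.array([cfg.r_bounds[0], x0, cfg.nu_bounds[0]])
    hi = np.array([cfg.r_bounds[1], k_hi, cfg.nu_bounds[1]])

    starts = []
    for r0 in cfg.r_grid:
        for kf in cfg.k_grid_factors:
            for nu0 in cfg.nu_grid:
                theta = np.clip(np.array([r0, kf * max_obs, nu0]), lo, hi)
                rss0 = float(np.sum(_residuals(theta, t, x, x0) ** 2))
                starts.append((rss0, tuple(theta)))
    # deterministic ranking; ties broken by the grid values themselves
    starts.sort(key=lambda s: (s[0], s[1]))

    best = None
    for _, theta0 in starts[: cfg.n_refine]:
        sol = least_squares(
            _residuals, np.asarray(theta0), args=(t, x, x0),
            bounds=(lo, hi), method="trf", max_nfev=cfg.max_nfev,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)

    rss, sol = best
    r_hat, k_hat, nu_hat = sol.x
    params = GrowthParams(x0=x0, r=float(r_hat), K=float(k_hat), nu=float(nu_hat))
    return FitResult(
        params=params,
        rss=rss,
        n_points=n,
        converged=bool(sol.success),
        never_doubles=never_doubles(params),
    )
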