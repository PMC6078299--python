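"""Seeded generators for periodic environments, strategies and densities.

Everything the other modules consume can be generated here reproducibly:
random nonnegative periodic rates (truncated harmonic series under an
amplitude budget), random sleep strategies with unit activity budget, and
smooth compactly-supported initial densities for the structured solver.
A deliberately naive left-endpoint Riemann integrator serves as the
independent fitness oracle against which the adaptive quadrature and the
closed forms are cross-checked.

All draws come from :func:`numpy.random.default_rng` seeded with
``(spec.seed, salt)`` where the salt is fixed per generator, so the same
spec reproduces every object bit for bit and different generators never
share a stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import (
    TWO_PI,
    EnvironmentSpec,
    ExposureMode,
    SleepStrategy,
    TabulatedRate,
    effective_birth_rate,
    effective_mortality_rate,
)

__all__ = [
    "SyntheticSpec",
    "SeparableBump",
    "random_environment",
    "random_sleep_strategy",
    "random_initial_density",
    "riemann_fitness_oracle",
]

_SALT_ENV = 1
_SALT_STRATEGY = 2
_SALT_DENSITY = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the random generators.

    Base-rate bounds reflect a population that grows on average (births
    exceed deaths) with modest foraging pressure; ``amplitude_budget`` caps
    the *sum* of relative harmonic amplitudes at each rate, which guarantees
    nonnegativity without clipping (clipping would distort the period-mean).
    ``n_grid`` is the tabulation resolution over one period.
    """

    seed: int = 0
    n_harmonics: int = 2
    birth_base: tuple[float, float] = (1.0, 2.0)
    mortality_base: tuple[float, float] = (0.2, 0.8)
    foraging_base: tuple[float, float] = (0.3, 1.0)
    amplitude_budget: float = 1.0
    period: float = TWO_PI
    n_grid: int = 256

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be at least 1")
        if not 0.0 <= self.amplitude_budget <= 1.0:
            raise ValueError(
                "amplitude_budget must lie in [0, 1]; larger budgets cannot "
                "guarantee nonnegative rates"
            )
        if self.period <= 0.0:
            raise ValueError("period must be positive")
        if self.n_grid < 8:
            raise ValueError("n_grid must be at least 8")


def _random_rate(rng: np.random.Generator, base_bounds, spec: SyntheticSpec) -> TabulatedRate:
    """One truncated harmonic series ``base*(1 + sum_k a_k cos(k w t - p_k))``.

    Raw amplitudes are rescaled so ``sum |a_k|`` equals a uniformly drawn
    fraction of the budget, keeping the series nonnegative everywhere.
    """
    base = rng.uniform(*base_bounds)
    k = spec.n_harmonics
    raw = rng.uniform(0.0, 1.0, size=k)
    total = rng.uniform(0.0, spec.amplitude_budget)
    amps = raw / raw.sum() * total if raw.sum() > 0 else np.zeros(k)
    phases = rng.uniform(0.0, TWO_PI, size=k)

    t = np.arange(spec.n_grid) * (spec.period / spec.n_grid)
    w = TWO_PI / spec.period
    vals = np.ones_like(t)
    for j in range(k):
        vals = vals + amps[j] * np.cos((j + 1) * w * t - phases[j])
    vals = base * vals
    # the budget guarantees this analytically; assert it numerically too
    if np.any(vals < -1e-12):
        raise AssertionError("amplitude budget failed to keep the rate nonnegative")
    return TabulatedRate(values=np.maximum(vals, 0.0), period=spec.period)


def random_environment(spec: SyntheticSpec) -> EnvironmentSpec:
    """Random tabulated environment (birth, mortality, foraging rates)."""
    rng = np.random.default_rng([spec.seed, _SALT_ENV])
    return EnvironmentSpec(
        birth=_random_rate(rng, spec.birth_base, spec),
        mortality=_random_rate(rng, spec.mortality_base, spec),
        foraging=_random_rate(rng, spec.foraging_base, spec),
        birth_coupled_to_activity=True,
    )


def random_sleep_strategy(spec: SyntheticSpec) -> SleepStrategy:
    """Random harmonic sleep strategy: depth uniform on [0,1], phase on [0,2pi)."""
    rng = np.random.default_rng([spec.seed, _SALT_STRATEGY])
    return SleepStrategy(
        rel_amp=rng.uniform(0.0, 1.0),
        phase=rng.uniform(0.0, TWO_PI),
        period=spec.period,
    )


@dataclass(frozen=True)
class SeparableBump:
    """Smooth compactly-supported initial density ``n0(tau, x)``.

    A product of two mollifier bumps ``exp(1 - 1/(1 - u^2))`` on
    ``|u| < 1`` with ``u = (z - center)/width``; infinitely smooth,
    nonnegative, and exactly zero outside ``(center - width, center + width)``
    in each coordinate — so the density vanishes near every domain edge.
    """

    tau_center: float
    tau_width: float
    x_center: float
    x_width: float
    amplitude: float = 1.0

    @staticmethod
    def _bump(z, center, width):
        u = (np.asarray(z, dtype=float) - center) / width
        out = np.zeros_like(u)
        inside = np.abs(u) < 1.0
        ui = u[inside]
        out[inside] = np.exp(1.0 - 1.0 / (1.0 - ui * ui))
        return out

    def __call__(self, tau, x):
        return (
            self.amplitude
            * self._bump(tau, self.tau_center, self.tau_width)
            * self._bump(x, self.x_center, self.x_width)
        )

    @property
    def tau_support(self) -> tuple[float, float]:
        return (self.tau_center - self.tau_width, self.tau_center + self.tau_width)

    @property
    def x_support(self) -> tuple[float, float]:
        return (self.x_center - self.x_width, self.x_center + self.x_width)


def random_initial_density(spec: SyntheticSpec, d: float, m: float) -> SeparableBump:
    """Random bump supported inside ``tau < d/2`` and ``x < m/4``.

    The support margins keep the absorbing-edge fluxes negligible over the
    default solver horizon.
    """
    rng = np.random.default_rng([spec.seed, _SALT_DENSITY])
    tau_c = rng.uniform(0.15, 0.35) * d
    tau_w = min(rng.uniform(0.05, 0.14) * d, tau_c * 0.95, (0.5 * d - tau_c) * 0.95)
    x_c = rng.uniform(0.08, 0.17) * m
    x_w = min(rng.uniform(0.02, 0.07) * m, x_c * 0.95, (0.25 * m - x_c) * 0.95)
    return SeparableBump(
        tau_center=tau_c,
        tau_width=tau_w,
        x_center=x_c,
        x_width=x_w,
        amplitude=rng.uniform(0.5, 2.0),
    )


def riemann_fitness_oracle(
    env: EnvironmentSpec,
    strategy,
    mode: ExposureMode,
    t: float,
    n_steps: int = 1_000_000,
) -> float:
    """Brute-force fitness: left-endpoint Riemann sum of the growth integrand.

    Deliberately independent of the adaptive quadrature and of the closed
    forms: a plain uniform sum of ``beta*s - gamma*f(s)`` over ``n_steps``
    panels.  When ``t`` is a whole number of periods the leading error term
    of the left-endpoint rule cancels (the integrand is periodic), making the
    oracle accurate far beyond its nominal first order.
    """
    if n_steps < 1_000:
        raise ValueError("n_steps must be at least 1000 for a credible oracle")
    if t == 0.0:
        return 0.0
    h = t / n_steps
    rho = np.arange(n_steps) * h
    integrand = effective_birth_rate(env, strategy, rho) - effective_mortality_rate(
        env, strategy, mode, rho
    )
    return float(h * integrand.sum())
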