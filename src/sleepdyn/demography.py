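"""Periodic vital rates, sleep strategies, and exposure models.

The demographic building blocks of the model: a basal birth rate ``beta(t)``,
basal mortality ``gamma(t)`` and basal foraging success ``alpha(t)``, each a
nonnegative periodic function of time, together with a sleep strategy ``s(t)``
that rescales them.  Activity weights births and foraging directly
(``beta*s``, ``alpha*s``); mortality is weighted by an exposure model
``f(s)`` that encodes whether sleeping is protective (safe, ``f = s``),
dangerous (vulnerable, ``f = max s - s``) or irrelevant (neutral, ``f = 1``).

The single-harmonic family ``base*(1 + rel_amp*cos(omega*t - phase))`` covers
every case treated analytically; tabulated rates/strategies (values on a
uniform grid over one period, linearly interpolated) cover general periodic
inputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "TWO_PI",
    "HarmonicRate",
    "TabulatedRate",
    "SleepStrategy",
    "TabulatedStrategy",
    "ExposureMode",
    "EnvironmentSpec",
    "rate_at",
    "activity_at",
    "activity_budget",
    "peak_activity",
    "exposure_weight",
    "effective_mortality_rate",
    "effective_birth_rate",
]


def _reduce_phase(phase: float) -> float:
    """Reduce an angular phase to [0, 2*pi)."""
    p = math.fmod(float(phase), TWO_PI)
    return p + TWO_PI if p < 0.0 else p


@dataclass(frozen=True)
class HarmonicRate:
    """Periodic demographic rate ``base * (1 + rel_amp * cos(omega*t - phase))``.

    ``base`` is the period-mean of the rate (births or deaths per unit time);
    ``rel_amp`` in [0, 1] is the relative modulation depth, which guarantees
    nonnegativity; ``phase`` (radians) shifts the peak; ``omega = 2*pi/period``.
    ``rel_amp = 0`` gives a constant rate.
    """

    base: float
    rel_amp: float = 0.0
    phase: float = 0.0
    period: float = TWO_PI

    def __post_init__(self) -> None:
        if self.base < 0.0:
            raise ValueError(f"base rate must be nonnegative, got {self.base}")
        if not 0.0 <= self.rel_amp <= 1.0:
            raise ValueError(
                f"rel_amp must lie in [0, 1] for a nonnegative rate, got {self.rel_amp}"
            )
        if self.period <= 0.0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "phase", _reduce_phase(self.phase))

    @property
    def omega(self) -> float:
        return TWO_PI / self.period

    def at(self, t):
        """Evaluate the rate at time ``t`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        return self.base * (1.0 + self.rel_amp * np.cos(self.omega * t - self.phase))

    @property
    def mean(self) -> float:
        """Period-mean of the rate (equals ``base``: the cosine averages out)."""
        return self.base


@dataclass(frozen=True)
class TabulatedRate:
    """Periodic rate given by values on a uniform grid over one period.

    ``values[k]`` is the rate at ``t = k * period / len(values)``; evaluation
    linearly interpolates with periodic wrap-around.  Values must be
    nonnegative.
    """

    values: np.ndarray
    period: float = TWO_PI

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("values must be a 1-D array with at least two samples")
        if np.any(vals < 0.0):
            raise ValueError("tabulated rate values must be nonnegative")
        if self.period <= 0.0:
            raise ValueError("period must be positive")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def at(self, t):
        t = np.asarray(t, dtype=float)
        k = self.values.size
        grid = np.linspace(0.0, self.period, k + 1)
        closed = np.concatenate([self.values, self.values[:1]])
        return np.interp(np.mod(t, self.period), grid, closed)

    @property
    def mean(self) -> float:
        # uniform periodic grid: trapezoid with wrap-around is the plain mean
        return float(np.mean(self.values))


@dataclass(frozen=True)
class SleepStrategy:
    """Harmonic activity schedule ``s(t) = 1 + rel_amp * cos(omega*t - phase)``.

    The period-mean of ``s`` is exactly 1: every strategy spends the same
    total activity per cycle, so strategies differ only in *when* they are
    active.  ``rel_amp = 0`` is the waking (never-sleeping) baseline;
    ``rel_amp = 1`` is full-depth sleep with activity touching zero once per
    cycle.
    """

    rel_amp: float = 1.0
    phase: float = 0.0
    period: float = TWO_PI

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_amp <= 1.0:
            raise ValueError(
                f"rel_amp must lie in [0, 1] for nonnegative activity, got {self.rel_amp}"
            )
        if self.period <= 0.0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "phase", _reduce_phase(self.phase))

    @property
    def omega(self) -> float:
        return TWO_PI / self.period

    def at(self, t):
        t = np.asarray(t, dtype=float)
        return 1.0 + self.rel_amp * np.cos(self.omega * t - self.phase)

    @property
    def budget(self) -> float:
        """Mean activity over one period (1 by construction)."""
        return 1.0

    @property
    def peak(self) -> float:
        """Maximum activity over one period: ``1 + rel_amp``."""
        return 1.0 + self.rel_amp


@dataclass(frozen=True)
class TabulatedStrategy:
    """General periodic activity schedule tabulated on a uniform grid.

    Same contract as :class:`TabulatedRate` plus the unit activity budget:
    the period-mean of the values must equal 1 (to 1e-9), so that tabulated
    and harmonic strategies are comparable like for like.  The peak used by
    the vulnerable exposure model is the grid maximum.
    """

    values: np.ndarray
    period: float = TWO_PI

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("values must be a 1-D array with at least two samples")
        if np.any(vals < 0.0):
            raise ValueError("activity values must be nonnegative")
        mean = float(np.mean(vals))
        if abs(mean - 1.0) > 1e-9:
            raise ValueError(
                f"strategy must have unit mean activity over one period, got {mean}"
            )
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def at(self, t):
        t = np.asarray(t, dtype=float)
        k = self.values.size
        grid = np.linspace(0.0, self.period, k + 1)
        closed = np.concatenate([self.values, self.values[:1]])
        return np.interp(np.mod(t, self.period), grid, closed)

    @property
    def budget(self) -> float:
        return float(np.mean(self.values))

    @property
    def peak(self) -> float:
        return float(np.max(self.values))


class ExposureMode(enum.Enum):
    """How activity maps to mortality exposure.

    * ``NEUTRAL`` — mortality is unaffected by sleep: ``f(s) = 1``.
    * ``SAFE`` — sleeping is protective (burrows, social sleeping):
      ``f(s) = s``, so low activity means low exposure.
    * ``VULNERABLE`` — sleeping is dangerous (open, solitary sleeping):
      ``f(s) = max s - s``, so low activity means high exposure.
    """

    NEUTRAL = "neutral"
    SAFE = "safe"
    VULNERABLE = "vulnerable"


@dataclass(frozen=True)
class EnvironmentSpec:
    """Basal birth, mortality and foraging rates sharing one period.

    ``birth_coupled_to_activity`` selects whether effective births are
    ``beta*s`` (mating success needs activity) or just ``beta`` (births are
    unaffected by sleep); both conventions occur in different ecological
    scenarios and the flag makes the choice explicit.
    """

    birth: HarmonicRate | TabulatedRate
    mortality: HarmonicRate | TabulatedRate
    foraging: HarmonicRate | TabulatedRate = field(
        default_factory=lambda: HarmonicRate(base=0.0)
    )
    birth_coupled_to_activity: bool = True

    def __post_init__(self) -> None:
        periods = {self.birth.period, self.mortality.period, self.foraging.period}
        if len({round(p, 12) for p in periods}) != 1:
            raise ValueError(f"all rates must share the same period, got {periods}")

    @property
    def period(self) -> float:
        return self.birth.period


def rate_at(rate, t):
    """Basal rate value at time ``t``."""
    return rate.at(t)


def activity_at(strategy, t):
    """Activity level ``s(t)``."""
    return strategy.at(t)


def activity_budget(strategy) -> float:
    """Mean activity over one period; 1 for every valid strategy."""
    return strategy.budget


def peak_activity(strategy) -> float:
    """Maximum of ``s`` over one period (``1 + rel_amp`` for harmonics)."""
    return strategy.peak


def exposure_weight(strategy, mode: ExposureMode, t):
    """Mortality weighting ``f(s)`` at time ``t`` under the given mode."""
    if mode is ExposureMode.NEUTRAL:
        return np.ones_like(np.asarray(t, dtype=float))
    if mode is ExposureMode.SAFE:
        return strategy.at(t)
    if mode is ExposureMode.VULNERABLE:
        return strategy.peak - strategy.at(t)
    raise ValueError(f"unknown exposure mode: {mode!r}")


def effective_mortality_rate(env: EnvironmentSpec, strategy, mode: ExposureMode, t):
    """Effective mortality ``gamma(t) * f(s)(t)``."""
    return env.mortality.at(t) * exposure_weight(strategy, mode, t)


def effective_birth_rate(env: EnvironmentSpec, strategy, t):
    """Effective birth rate: ``beta(t)*s(t)`` if coupled, else ``beta(t)``."""
    b = env.birth.at(t)
    if env.birth_coupled_to_activity:
        return b * strategy.at(t)
    return b
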