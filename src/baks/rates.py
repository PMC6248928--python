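"""Parametric ground-truth firing-rate functions.

Five families of time-varying intensity lambda(t), in spikes/s, are used to
drive the renewal-process spike simulators and to score rate estimates:

``chirp``
    eta + A*sin(2*pi*f*t**2 + phi) — oscillation whose instantaneous
    frequency grows linearly in time (heterogeneous-frequency process).
``sine``
    eta + A*sin(2*pi*f*t + phi) — homogeneous oscillation.
``sawtooth``
    eta + (2*A/pi)*arctan(cot(pi*f*t + phi)) — a linear ramp with periodic
    discontinuities, evaluated through the exact piecewise identity
    arctan(cot(x)) = pi/2 - (x mod pi) so that the cotangent poles never
    produce NaN; at a discontinuity the right-limit value is returned.
``gds``
    eta + eta*A*exp(-(t-t0)**2/(2*sigma_env**2))*sin(2*pi*f*t + phi) —
    Gaussian-damped sinusoid; here ``amp`` is a dimensionless multiplier of
    the base rate eta.
``square``
    eta + A*sign(sin(2*pi*f*t + phi)) with sign(0) -> +1 — discontinuous
    two-level rate with sudden jumps.

Here eta > 0 is the base (average) rate, A >= 0 the amplitude, f > 0 the
frequency in Hz, and phi the phase in radians.  All times are seconds.
Parameter combinations that would make the rate negative anywhere are
rejected at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

RATE_KINDS = ("chirp", "sine", "sawtooth", "gds", "square")

__all__ = [
    "RATE_KINDS",
    "RateParams",
    "RateCurve",
    "rate_values",
    "evaluate_rate",
    "cumulative_intensity",
    "time_grid",
]


@dataclass(frozen=True)
class RateParams:
    """Parameters of one ground-truth rate function.

    ``amp`` is in spikes/s for the additive families (chirp, sine, sawtooth,
    square) and dimensionless for ``gds``; ``t0`` and ``sigma_env`` (the
    Gaussian-envelope center and width, in seconds) apply to ``gds`` only.
    """

    kind: str
    eta: float
    amp: float
    freq: float
    phase: float = 0.0
    t0: float | None = None
    sigma_env: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in RATE_KINDS:
            raise ValueError(
                f"unknown rate kind {self.kind!r}; expected one of {RATE_KINDS}"
            )
        if not self.eta > 0:
            raise ValueError("base rate eta must be positive")
        if not self.freq > 0:
            raise ValueError("frequency must be positive")
        if self.amp < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.kind == "gds":
            if self.t0 is None or self.sigma_env is None:
                raise ValueError("gds rate requires t0 and sigma_env")
            if not self.sigma_env > 0:
                raise ValueError("sigma_env must be positive")
            # min over t of eta*(1 + amp*envelope*sin) is eta*(1 - amp)
            if self.amp > 1:
                raise ValueError(
                    "gds amplitude > 1 would drive the rate negative "
                    f"(minimum eta*(1-amp) = {self.eta * (1 - self.amp):g})"
                )
        else:
            # additive families attain eta - amp (sawtooth approaches it)
            if self.amp > self.eta:
                raise ValueError(
                    "amplitude exceeds base rate: minimum rate "
                    f"{self.eta - self.amp:g} spikes/s would be negative"
                )


@dataclass(frozen=True)
class RateCurve:
    """A rate function sampled on a uniform time grid.

    ``times`` is strictly increasing and uniformly spaced with step ``dt``
    (seconds); ``values`` are nonnegative rates in spikes/s.
    """

    times: np.ndarray
    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if v.shape != t.shape:
            raise ValueError("times and values must have equal length")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        steps = np.diff(t)
        if t.size > 1 and not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-12):
            raise ValueError("times must be uniformly spaced with step dt")
        if np.any(v < 0):
            raise ValueError("rate values must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def time_grid(duration: float, dt: float = 1e-3) -> np.ndarray:
    """Uniform grid 0, dt, ..., duration (inclusive of both endpoints)."""
    if not duration > 0 or not dt > 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    if n < 1:
        raise ValueError("dt larger than duration")
    return np.linspace(0.0, n * dt, n + 1)


def rate_values(params: RateParams, times) -> np.ndarray:
    """Evaluate lambda(t) at arbitrary times (no grid requirement)."""
    t = np.asarray(times, dtype=float)
    if params.kind == "chirp":
        out = params.eta + params.amp * np.sin(
            2 * np.pi * params.freq * t * t + params.phase
        )
    elif params.kind == "sine":
        out = params.eta + params.amp * np.sin(
            2 * np.pi * params.freq * t + params.phase
        )
    elif params.kind == "sawtooth":
        x = np.pi * params.freq * t + params.phase
        # arctan(cot(x)) = pi/2 - (x mod pi); mod -> 0 at poles, i.e. the
        # right-limit value pi/2 at each discontinuity
        out = params.eta + (2 * params.amp / np.pi) * (np.pi / 2 - np.mod(x, np.pi))
    elif params.kind == "gds":
        envelope = np.exp(-((t - params.t0) ** 2) / (2 * params.sigma_env**2))
        out = params.eta * (
            1.0
            + params.amp * envelope * np.sin(2 * np.pi * params.freq * t + params.phase)
        )
    else:  # square
        s = np.sin(2 * np.pi * params.freq * t + params.phase)
        out = params.eta + params.amp * np.where(s >= 0, 1.0, -1.0)
    if np.any(out < 0):
        bad = t[np.argmax(out < 0)]
        raise ValueError(f"rate is negative at t = {bad:g} s")
    return out


def evaluate_rate(params: RateParams, times) -> RateCurve:
    """Sample lambda(t) on a uniform grid, returning a :class:`RateCurve`."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times must contain at least two grid points")
    dt = float(t[1] - t[0])
    return RateCurve(times=t, values=rate_values(params, t), dt=dt)


def cumulative_intensity(params: RateParams, times, multiplier: float = 1.0) -> np.ndarray:
    """Integrated intensity Lambda(t) = multiplier * int_0^t lambda(u) du.

    Computed by cumulative trapezoidal quadrature on the supplied grid, which
    must start at 0 and be strictly increasing.  The multiplier is the
    renewal shape parameter gamma for the inhomogeneous-Gamma model and 1 for
    the inverse-Gaussian model.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times must contain at least two grid points")
    if abs(t[0]) > 1e-12:
        raise ValueError("grid must start at t = 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("grid must be strictly increasing")
    if not multiplier > 0:
        raise ValueError("multiplier must be positive")
    lam = rate_values(params, t)
    out = multiplier * cumulative_trapezoid(lam, t, initial=0.0)
    # guard against float round-off producing tiny decreases where lambda ~ 0
    return np.maximum.accumulate(out)
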