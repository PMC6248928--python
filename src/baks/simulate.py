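"""Renewal-process spike-train simulators.

Spike trains are generated from inhomogeneous Gamma (IG) and inhomogeneous
inverse-Gaussian (IIG) renewal models by the time-rescaling construction:
i.i.d. inter-spike intervals (ISIs) are drawn in the rescaled domain — from
Gamma(shape=gamma, scale=theta) for IG or inverse-Gaussian(mu, shape=gamma)
for IIG — their partial sums are mapped back through the inverse of the
integrated intensity Lambda(t), and generation stops at the first rescaled
time beyond Lambda(T).  For IG the rescaling multiplies the intensity
integral by gamma; for IIG the plain integral is used.

The renewal process starts fresh at t = 0 (no stationary first-interval
correction), and events are confined to the half-open window (0, T].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rates import RateParams, cumulative_intensity, time_grid

MODEL_FAMILIES = ("IG", "IIG")

__all__ = [
    "MODEL_FAMILIES",
    "SpikeTrain",
    "RenewalModelParams",
    "sample_inverse_gaussian",
    "sample_renewal_isis",
    "invert_intensity",
    "generate_spike_train",
    "pool_trials",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) within a recording window (0, duration].

    The train may be empty; downstream estimators reject empty trains
    explicitly since the adaptive bandwidth is undefined without spikes.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if t.size:
            if np.any(t <= 0) or np.any(t > self.duration * (1 + 1e-12)):
                raise ValueError("spike times must lie in (0, duration]")
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def shifted(self, offset: float) -> "SpikeTrain":
        """Train translated by ``offset`` seconds (window grows to fit)."""
        return SpikeTrain(self.times + offset, self.duration + offset)


@dataclass(frozen=True)
class RenewalModelParams:
    """ISI family and parameters of a renewal spike model.

    IG uses Gamma ISIs with ``shape`` gamma and ``scale`` theta; IIG uses
    inverse-Gaussian ISIs with ``shape`` gamma and ``location`` mu (the
    distribution mean).  shape = 1 with scale = 1 reduces IG to the
    inhomogeneous Poisson process.
    """

    family: str
    shape: float
    scale: float | None = None
    location: float | None = None

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}")
        if not self.shape > 0:
            raise ValueError("shape parameter must be positive")
        if self.family == "IG":
            if self.scale is None or not self.scale > 0:
                raise ValueError("IG model requires a positive scale (theta)")
        else:
            if self.location is None or not self.location > 0:
                raise ValueError("IIG model requires a positive location (mu)")

    @property
    def mean_rescaled_isi(self) -> float:
        if self.family == "IG":
            return self.shape * self.scale
        return self.location

    @property
    def intensity_multiplier(self) -> float:
        """Multiplier of the intensity integral in the time rescaling."""
        return self.shape if self.family == "IG" else 1.0


def sample_inverse_gaussian(mu: float, lam: float, rng: np.random.Generator, size=None):
    """Draw from the inverse-Gaussian distribution IG(mean=mu, shape=lam).

    Uses the Michael–Schucany–Haas transformation: a chi-square variate is
    mapped to the smaller root of the quadratic defining the distribution,
    which is then accepted with probability mu/(mu + root), otherwise the
    conjugate root mu^2/root is returned.  Returns a scalar when ``size`` is
    None, else an array of the requested shape.
    """
    if not mu > 0 or not lam > 0:
        raise ValueError("mu and lam must be positive")
    scalar = size is None
    nu = rng.standard_normal(1 if scalar else size)
    y = nu * nu
    x = (
        mu
        + (mu * mu * y) / (2.0 * lam)
        - (mu / (2.0 * lam)) * np.sqrt(4.0 * mu * lam * y + (mu * y) ** 2)
    )
    u = rng.uniform(size=x.shape)
    out = np.where(u <= mu / (mu + x), x, mu * mu / x)
    return float(out[0]) if scalar else out


def sample_renewal_isis(
    model: RenewalModelParams, count: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. rescaled-domain ISIs from the model's ISI distribution."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if model.family == "IG":
        return rng.gamma(model.shape, model.scale, size=count)
    return sample_inverse_gaussian(model.location, model.shape, rng, size=count)


def invert_intensity(intensity_times, intensity_values, targets) -> np.ndarray:
    """Map rescaled times back through Lambda^{-1} by linear interpolation.

    ``intensity_values`` must be nondecreasing with value 0 at the first grid
    point.  Targets beyond Lambda(T) fall outside the recording window and
    are dropped; a target exactly at Lambda(T) maps to T.
    """
    t = np.asarray(intensity_times, dtype=float)
    lam = np.asarray(intensity_values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if t.shape != lam.shape or t.ndim != 1:
        raise ValueError("intensity grid and values must be equal-length 1-D")
    if np.any(np.diff(lam) < 0):
        raise ValueError("integrated intensity must be nondecreasing")
    if abs(lam[0]) > 1e-9:
        raise ValueError("integrated intensity must start at 0")
    if targets.size and np.any(np.diff(targets) < 0):
        raise ValueError("targets must be nondecreasing")
    total = lam[-1]
    kept = targets[targets <= total * (1 + 1e-12)]
    kept = np.minimum(kept, total)
    return np.interp(kept, lam, t)


def _strictly_increasing(times: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Nudge tied values upward so the sequence is strictly increasing."""
    if times.size < 2:
        return times
    out = times.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def generate_spike_train(
    rate: RateParams,
    model: RenewalModelParams,
    duration: float,
    rng: np.random.Generator,
    dt: float = 1e-3,
) -> SpikeTrain:
    """Simulate one spike train on (0, duration] via time rescaling.

    Rescaled ISIs are drawn in blocks sized ~1.5 * Lambda(T) / E[ISI] and
    extended if exhausted, so coverage of the window is guaranteed without
    unbounded loops.  Exact ties after inversion (possible at float
    resolution) are perturbed by 1 ns to preserve strict ordering.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    grid = time_grid(duration, dt)
    lam_cum = cumulative_intensity(rate, grid, model.intensity_multiplier)
    total = lam_cum[-1]
    if total <= 0:
        return SpikeTrain(np.empty(0), duration)

    block = max(16, math.ceil(1.5 * total / model.mean_rescaled_isi))
    isis = sample_renewal_isis(model, block, rng)
    rescaled = np.cumsum(isis)
    while rescaled[-1] <= total:
        more = sample_renewal_isis(model, block, rng)
        rescaled = np.concatenate([rescaled, rescaled[-1] + np.cumsum(more)])
    rescaled = rescaled[rescaled <= total]
    if rescaled.size == 0:
        return SpikeTrain(np.empty(0), duration)

    times = invert_intensity(grid, lam_cum, rescaled)
    times = times[(times > 0) & (times <= duration)]
    times = _strictly_increasing(times)
    times = times[times <= duration]
    return SpikeTrain(times, duration)


def pool_trials(trains: list[SpikeTrain]) -> SpikeTrain:
    """Superimpose trials into one train (merged sorted times).

    All trains must share the same recording duration.  Coincident spikes
    from different trials are nudged apart by 1 ns to keep the merged
    sequence strictly increasing.
    """
    if not trains:
        raise ValueError("need at least one train to pool")
    duration = trains[0].duration
    for tr in trains[1:]:
        if tr.duration != duration:
            raise ValueError(
                f"mismatched durations: {tr.duration} != {duration}"
            )
    merged = np.sort(np.concatenate([tr.times for tr in trains]))
    merged = _strictly_increasing(merged)
    merged = merged[merged <= duration]
    return SpikeTrain(merged, duration)
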