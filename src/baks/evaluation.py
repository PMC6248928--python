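"""MISE benchmarking and prior-shape (alpha) tuning.

The estimator is scored against a known ground-truth rate by the integrated
squared error ISE = dt * sum_t (lambda_hat(t) - lambda(t))^2 over the
observation window, averaged across repeated simulated spike trains to give
the MISE with a normal-approximation 95% confidence interval.

``tune_alpha`` reproduces the hyperparameter-tuning protocol: for a grid of
prior shapes alpha it estimates the *same* set of generated trains at every
alpha (beta fixed to the n^(4/5) rule), computes per-scenario MISE curves,
and selects the alpha minimizing the across-scenario average, ties broken
toward the smallest alpha.

``table1_presets`` is a programmatic registry of the synthetic benchmark
scenarios: six tuning scenarios (IG and IIG renewal models crossed with
chirp, sine and sawtooth rates at medium intensity eta=50, A=25 and medium
frequency f = 0.5/1/1), and the testing-1..5 variations of intensity,
frequency, ISI shape gamma, trial count and the Gaussian-damped-sinusoid
rate.  All scenarios use a 2 s window, IG(gamma=4, theta=1) and
IIG(gamma=4, mu=1) unless the variation says otherwise, and the phases
chirp 0, sine -pi/2, sawtooth -pi/4, gds -pi/2.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import BETA_RULE, BAKSConfig, default_beta
from .rates import RateCurve, RateParams, rate_values, time_grid
from .simulate import RenewalModelParams, SpikeTrain, generate_spike_train, pool_trials

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "MISEResult",
    "TuneResult",
    "integrated_squared_error",
    "weighted_mise",
    "mise_experiment",
    "tune_alpha",
    "table1_presets",
    "tuning_scenarios",
]

#: phases applied to every scenario, per rate-function family
PHASES = {
    "chirp": 0.0,
    "sine": -np.pi / 2,
    "sawtooth": -np.pi / 4,
    "gds": -np.pi / 2,
}

#: frequencies (Hz) per family at the low/medium/high settings
FREQUENCIES = {
    "chirp": {"low": 0.25, "medium": 0.5, "high": 0.75},
    "sine": {"low": 0.5, "medium": 1.0, "high": 1.5},
    "sawtooth": {"low": 0.5, "medium": 1.0, "high": 1.5},
}

MAX_REDRAWS = 100


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic benchmark configuration."""

    label: str
    rate: RateParams
    model: RenewalModelParams
    duration: float = 2.0
    repetitions: int = 100
    trials_per_repetition: int = 1

    def __post_init__(self) -> None:
        if self.repetitions < 1 or self.trials_per_repetition < 1:
            raise ValueError("repetitions and trials_per_repetition must be >= 1")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class MISEResult:
    """Per-repetition ISEs with their mean and 95% CI half-width."""

    ise_per_repetition: np.ndarray
    mise: float
    ci95: float


@dataclass(frozen=True)
class TuneResult:
    """Output of the alpha-tuning sweep."""

    selected_alpha: float
    table: pd.DataFrame  # columns: scenario, alpha, mise, ci95
    average: pd.DataFrame  # columns: alpha, mise (across-scenario mean)
    per_scenario_minimizer: dict[str, float]


def integrated_squared_error(estimate: RateCurve, truth: RateCurve) -> float:
    """ISE = dt * sum (estimate - truth)^2 over the shared grid."""
    if estimate.times.shape != truth.times.shape or not np.allclose(
        estimate.times, truth.times
    ):
        raise ValueError("estimate and truth must share the same time grid")
    diff = estimate.values - truth.values
    return float(estimate.dt * np.sum(diff * diff))


def weighted_mise(
    estimate: RateCurve,
    reference: RateCurve,
    upper: RateCurve,
    lower: RateCurve,
) -> float:
    """ISE with the pointwise error normalized by credible-interval width.

    Where the estimate is at or above the reference the error is divided by
    ``upper``; below, by ``lower``.  Both interval curves must be strictly
    positive.
    """
    for other in (reference, upper, lower):
        if other.times.shape != estimate.times.shape or not np.allclose(
            other.times, estimate.times
        ):
            raise ValueError("all curves must share the same time grid")
    if np.any(upper.values <= 0) or np.any(lower.values <= 0):
        raise ValueError("credible-interval values must be strictly positive")
    width = np.where(
        estimate.values >= reference.values, upper.values, lower.values
    )
    z = (estimate.values - reference.values) / width
    return float(estimate.dt * np.sum(z * z))


def _scenario_key(scenario: ScenarioSpec) -> int:
    """Stable per-scenario substream key (CRC32 of the label, < 2^31)."""
    return zlib.crc32(scenario.label.encode()) & 0x7FFFFFFF


def _draw_repetition(
    scenario: ScenarioSpec, seed: int, rep: int, dt: float
) -> SpikeTrain:
    """One (possibly pooled) train; zero-spike draws are retried.

    Substreams are keyed on (seed, scenario label, repetition, attempt), so
    the same scenario yields the same trains whether it is scored alone or
    inside a tuning sweep.
    """
    key = _scenario_key(scenario)
    for attempt in range(MAX_REDRAWS):
        rng = np.random.default_rng([seed, key, rep, attempt])
        trains = [
            generate_spike_train(scenario.rate, scenario.model, scenario.duration, rng, dt)
            for _ in range(scenario.trials_per_repetition)
        ]
        pooled = pool_trials(trains) if len(trains) > 1 else trains[0]
        if pooled.n > 0:
            return pooled
        logger.warning(
            "scenario %s repetition %d attempt %d produced no spikes; redrawing",
            scenario.label,
            rep,
            attempt,
        )
    raise RuntimeError(
        f"scenario {scenario.label!r}: no spikes after {MAX_REDRAWS} redraws"
    )


def _ise_over_alphas(
    spikes: SpikeTrain,
    times: np.ndarray,
    dt: float,
    truth_values: np.ndarray,
    alphas: np.ndarray,
    beta,
    scale: float = 1.0,
) -> np.ndarray:
    """ISE of the BAKS estimate of one train at each alpha.

    The spike-to-grid distance matrix is formed once and shared across the
    alpha grid; bandwidth sums are log-sum-exp reductions of it.  ``scale``
    multiplies the kernel estimate before scoring: a train pooled from k
    trials estimates k times the per-trial intensity, so its estimate is
    scored with scale = 1/k against the single-trial ground truth.
    """
    beta_val = default_beta(spikes.n) if isinstance(beta, str) else float(beta)
    d = times[:, None] - spikes.times[None, :]
    half_d2 = 0.5 * d * d
    logc = np.log(half_d2 + 1.0 / beta_val)
    out = np.empty(alphas.size)
    for j, a in enumerate(alphas):
        log_num = logsumexp(-a * logc, axis=1)
        log_den = logsumexp(-(a + 0.5) * logc, axis=1)
        h = np.exp(gammaln(a) - gammaln(a + 0.5) + log_num - log_den)
        rate = scale * np.exp(-half_d2 / (h * h)[:, None]).sum(axis=1) / (
            np.sqrt(2 * np.pi) * h
        )
        diff = rate - truth_values
        out[j] = dt * np.sum(diff * diff)
    return out


def _summarize(ises: np.ndarray) -> MISEResult:
    mise = float(np.mean(ises))
    se = float(np.std(ises, ddof=1) / np.sqrt(ises.size)) if ises.size > 1 else 0.0
    return MISEResult(ise_per_repetition=ises, mise=mise, ci95=1.96 * se)


def mise_experiment(
    scenario: ScenarioSpec,
    config: BAKSConfig,
    seed: int,
    dt: float = 1e-3,
) -> MISEResult:
    """MISE of BAKS on one scenario over its configured repetitions.

    Each repetition generates (and pools, when trials_per_repetition > 1) a
    fresh train from a substream derived from ``seed`` and the repetition
    index, estimates the rate on a dt grid over [0, duration], and scores
    the ISE against the true rate on the same grid.
    """
    times = time_grid(scenario.duration, dt)
    truth = rate_values(scenario.rate, times)
    alphas = np.asarray([config.alpha])
    scale = 1.0 / scenario.trials_per_repetition
    ises = np.empty(scenario.repetitions)
    for rep in range(scenario.repetitions):
        train = _draw_repetition(scenario, seed, rep, dt)
        ises[rep] = _ise_over_alphas(
            train, times, dt, truth, alphas, config.beta, scale
        )[0]
    return _summarize(ises)


def tune_alpha(
    alpha_grid,
    scenarios: list[ScenarioSpec],
    seed: int,
    beta=BETA_RULE,
    dt: float = 1e-3,
) -> TuneResult:
    """Sweep the prior shape alpha over benchmark scenarios and pick the best.

    For every scenario the same generated trains are scored at every alpha
    on the grid; the winner minimizes the across-scenario average MISE, with
    ties broken toward the smallest alpha.  The full long-format MISE table
    is returned for plotting MISE-versus-alpha curves.
    """
    alphas = np.asarray(alpha_grid, dtype=float)
    if alphas.size == 0:
        raise ValueError("alpha grid must be nonempty")
    if np.any(alphas <= 0):
        raise ValueError("alpha values must be positive")
    if not scenarios:
        raise ValueError("need at least one scenario")

    rows = []
    per_scenario_mise = np.empty((len(scenarios), alphas.size))
    minimizers: dict[str, float] = {}
    for s_idx, scen in enumerate(scenarios):
        times = time_grid(scen.duration, dt)
        truth = rate_values(scen.rate, times)
        scale = 1.0 / scen.trials_per_repetition
        ises = np.empty((scen.repetitions, alphas.size))
        for rep in range(scen.repetitions):
            train = _draw_repetition(scen, seed, rep, dt)
            ises[rep] = _ise_over_alphas(train, times, dt, truth, alphas, beta, scale)
        mise = ises.mean(axis=0)
        ci95 = 1.96 * ises.std(axis=0, ddof=1) / np.sqrt(scen.repetitions)
        per_scenario_mise[s_idx] = mise
        minimizers[scen.label] = float(alphas[int(np.argmin(mise))])
        for j, a in enumerate(alphas):
            rows.append(
                {"scenario": scen.label, "alpha": float(a), "mise": mise[j], "ci95": ci95[j]}
            )

    average = per_scenario_mise.mean(axis=0)
    selected = float(alphas[int(np.argmin(average))])  # argmin takes first tie
    return TuneResult(
        selected_alpha=selected,
        table=pd.DataFrame(rows),
        average=pd.DataFrame({"alpha": alphas, "mise": average}),
        per_scenario_minimizer=minimizers,
    )


def _medium_rate(kind: str) -> RateParams:
    return RateParams(
        kind=kind, eta=50.0, amp=25.0, freq=FREQUENCIES[kind]["medium"], phase=PHASES[kind]
    )


def _model(family: str, gamma: float = 4.0) -> RenewalModelParams:
    if family == "IG":
        return RenewalModelParams(family="IG", shape=gamma, scale=1.0)
    return RenewalModelParams(family="IIG", shape=gamma, location=1.0)


def table1_presets() -> dict[str, ScenarioSpec]:
    """Registry of every tuning and testing-1..5 benchmark scenario.

    Keys follow ``phase/model/...`` (e.g. ``tuning/IG/sine``,
    ``testing3/IIG/gamma7/chirp``, ``testing4/IG/trials20/sawtooth``,
    ``testing5/IG/gds/high_frequency``).  For testing2 and testing5,
    model-less aliases (``testing2/low_intensity/chirp``) resolve to the IG
    model.
    """
    presets: dict[str, ScenarioSpec] = {}

    def add(key: str, rate: RateParams, model: RenewalModelParams, trials: int = 1):
        presets[key] = ScenarioSpec(
            label=key,
            rate=rate,
            model=model,
            duration=2.0,
            repetitions=100,
            trials_per_repetition=trials,
        )

    for family in ("IG", "IIG"):
        for kind in ("chirp", "sine", "sawtooth"):
            med = _medium_rate(kind)
            add(f"tuning/{family}/{kind}", med, _model(family))
            add(f"testing1/{family}/{kind}", med, _model(family))
            variants = {
                "low_intensity": dataclasses.replace(med, eta=11.0, amp=9.0),
                "high_intensity": dataclasses.replace(med, eta=100.0, amp=75.0),
                "low_frequency": dataclasses.replace(med, freq=FREQUENCIES[kind]["low"]),
                "high_frequency": dataclasses.replace(med, freq=FREQUENCIES[kind]["high"]),
            }
            for name, rp in variants.items():
                add(f"testing2/{family}/{name}/{kind}", rp, _model(family))
            for g in range(1, 11):
                add(f"testing3/{family}/gamma{g}/{kind}", med, _model(family, float(g)))
            for tr in (5, 10, 20, 30):
                add(f"testing4/{family}/trials{tr}/{kind}", med, _model(family), trials=tr)

        gds_variants = {
            "low_intensity": (10.0, 1.0),
            "medium_intensity": (50.0, 1.0),
            "high_intensity": (100.0, 1.0),
            "low_frequency": (50.0, 0.5),
            "medium_frequency": (50.0, 1.5),
            "high_frequency": (50.0, 2.0),
        }
        for name, (eta, f) in gds_variants.items():
            rp = RateParams(
                kind="gds",
                eta=eta,
                amp=1.0,
                freq=f,
                phase=PHASES["gds"],
                t0=0.2,
                sigma_env=1.0,
            )
            add(f"testing5/{family}/gds/{name}", rp, _model(family))

    # model-less aliases default to the IG model
    for key in list(presets):
        parts = key.split("/")
        if parts[0] in ("testing2", "testing5") and parts[1] == "IG":
            alias = "/".join([parts[0]] + parts[2:])
            presets[alias] = dataclasses.replace(presets[key], label=alias)
    return presets


def tuning_scenarios(repetitions: int = 100) -> list[ScenarioSpec]:
    """The six tuning scenarios, in IG-then-IIG, chirp/sine/sawtooth order."""
    presets = table1_presets()
    keys = [
        f"tuning/{family}/{kind}"
        for family in ("IG", "IIG")
        for kind in ("chirp", "sine", "sawtooth")
    ]
    return [
        dataclasses.replace(presets[k], repetitions=repetitions) for k in keys
    ]
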