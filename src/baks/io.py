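"""File formats and run configuration.

Spike trains travel as plain text (one event time in seconds per line) or,
for multi-trial recordings, as a two-column CSV with header
``trial_id,time_s``.  Curves are CSV with fixed 9-decimal formatting:
``time_s,rate_hz`` for a rate curve, ``time_s,bandwidth_s`` for a bandwidth
curve, and ``time_s,bandwidth_s,rate_hz`` for a full estimate.  Run
configuration files are YAML or JSON with the keys ``rate:``, ``model:``,
``baks:``, ``seed``, ``duration`` and ``dt``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BAKSConfig, BandwidthCurve
from .rates import RateCurve, RateParams
from .simulate import RenewalModelParams, SpikeTrain

__all__ = [
    "read_spike_trains",
    "write_spike_train",
    "write_trials_csv",
    "write_curve",
    "read_rate_curve",
    "write_estimate",
    "load_config",
    "rate_from_mapping",
    "model_from_mapping",
    "baks_from_mapping",
]

_FMT = "%.9f"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("txt", "csv"):
            raise ValueError('format must be "txt" or "csv"')
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "txt"


def read_spike_trains(
    path, fmt: str | None = None, duration: float | None = None
) -> list[SpikeTrain]:
    """Read one (txt) or several (csv) spike trains from disk.

    When ``duration`` is omitted it is taken as the largest observed time
    rounded up to the next integer second.  Negative or unsorted times are
    reported with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)

    if fmt == "txt":
        groups: dict[object, list[tuple[int, float]]] = {0: []}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    value = float(line)
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: not a number: {line!r}") from err
                groups[0].append((lineno, value))
    else:
        frame = pd.read_csv(path)
        expected = ["trial_id", "time_s"]
        if list(frame.columns[:2]) != expected:
            raise ValueError(
                f"{path}: expected columns {expected}, found {list(frame.columns)}"
            )
        groups = {}
        for row_idx, (trial, value) in enumerate(
            zip(frame["trial_id"], frame["time_s"])
        ):
            groups.setdefault(trial, []).append((row_idx + 2, float(value)))

    if all(not entries for entries in groups.values()):
        raise ValueError(f"{path}: no spike times found")

    all_times = [v for entries in groups.values() for _, v in entries]
    resolved = duration if duration is not None else float(math.ceil(max(all_times)))

    trains = []
    for trial in sorted(groups, key=str):
        entries = groups[trial]
        for (ln_prev, prev), (ln, cur) in zip(entries, entries[1:]):
            if cur <= prev:
                raise ValueError(
                    f"{path}:{ln}: spike times not strictly increasing "
                    f"({cur} after {prev})"
                )
        for ln, v in entries:
            if v <= 0:
                raise ValueError(f"{path}:{ln}: spike time must be positive, got {v}")
            if v > resolved:
                raise ValueError(
                    f"{path}:{ln}: spike time {v} exceeds duration {resolved}"
                )
        trains.append(SpikeTrain(np.asarray([v for _, v in entries]), resolved))
    return trains


def write_spike_train(path, train: SpikeTrain) -> None:
    """One event time per line, 9 decimal places."""
    np.savetxt(path, train.times, fmt=_FMT)


def write_trials_csv(path, trains: list[SpikeTrain]) -> None:
    """Multi-trial CSV with header trial_id,time_s."""
    frame = pd.DataFrame(
        [
            {"trial_id": idx, "time_s": t}
            for idx, train in enumerate(trains)
            for t in train.times
        ],
        columns=["trial_id", "time_s"],
    )
    frame.to_csv(path, index=False, float_format=_FMT)


def write_curve(path, curve) -> None:
    """Write a RateCurve (time_s,rate_hz) or BandwidthCurve (time_s,bandwidth_s)."""
    if isinstance(curve, RateCurve):
        header, values = "time_s,rate_hz", curve.values
    elif isinstance(curve, BandwidthCurve):
        header, values = "time_s,bandwidth_s", curve.h_values
    else:
        raise TypeError(f"cannot serialize {type(curve).__name__}")
    data = np.column_stack([curve.times, values])
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=header, comments="")


def read_rate_curve(path) -> RateCurve:
    frame = pd.read_csv(path)
    if list(frame.columns) != ["time_s", "rate_hz"]:
        raise ValueError(f"{path}: expected columns time_s,rate_hz")
    t = frame["time_s"].to_numpy()
    return RateCurve(times=t, values=frame["rate_hz"].to_numpy(), dt=float(t[1] - t[0]))


def write_estimate(path, bandwidth: BandwidthCurve, rate: RateCurve) -> None:
    """Full estimate CSV: time_s,bandwidth_s,rate_hz."""
    if bandwidth.times.shape != rate.times.shape or not np.allclose(
        bandwidth.times, rate.times
    ):
        raise ValueError("bandwidth and rate curves must share the same grid")
    data = np.column_stack([rate.times, bandwidth.h_values, rate.values])
    np.savetxt(
        path, data, fmt=_FMT, delimiter=",", header="time_s,bandwidth_s,rate_hz",
        comments="",
    )


def load_config(path) -> dict:
    """Load a YAML or JSON run-configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def rate_from_mapping(mapping: dict) -> RateParams:
    """Build RateParams from a config ``rate:`` section."""
    allowed = {"kind", "eta", "amp", "freq", "phase", "t0", "sigma_env"}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown rate keys: {sorted(unknown)}")
    return RateParams(**mapping)


def model_from_mapping(mapping: dict) -> RenewalModelParams:
    """Build RenewalModelParams from a config ``model:`` section."""
    allowed = {"family", "shape", "scale", "location"}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown model keys: {sorted(unknown)}")
    return RenewalModelParams(**mapping)


def baks_from_mapping(mapping: dict) -> BAKSConfig:
    """Build BAKSConfig from a config ``baks:`` section."""
    allowed = {"alpha", "beta"}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown baks keys: {sorted(unknown)}")
    return BAKSConfig(**mapping)
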