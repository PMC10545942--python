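"""Stimulation waveforms, state logs, clock drift, and sensor calibration.

Optogenetic rigs of the kind this package serves split work across two
controllers: a microcontroller drives the LED matrices from a firmware
protocol (intensity ramp or on/off blinking) while the acquisition
computer timestamps every reported state change into a CSV log.  The two
clocks run free, diverging at a constant rate (a few seconds per hour is
typical), so aligning stimulus epochs to video frames needs a linear
drift model estimated from paired timestamps.

Also here: the causal moving-average filter applied to distance-sensor
readings, and the quadratic illuminance→irradiance calibration that turns
lux-sensor readings into approximate irradiance (µW/mm²) on the arena.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ProtocolParams",
    "StimulusTimeline",
    "LogRecord",
    "DriftModel",
    "QuadraticFit",
    "intensity_ramp",
    "blinking",
    "moving_average",
    "write_state_log",
    "parse_state_log",
    "estimate_drift",
    "frame_states",
    "fit_quadratic",
    "apply_calibration",
]


@dataclass(frozen=True)
class ProtocolParams:
    """Firmware protocol knobs.

    max_value    : top byte value the ramp counts up to (0–255).
    interval     : seconds between protocol steps (the firmware's step delay).
    interval_low : initial off period in seconds before blinking starts.
    brightness   : byte value driven during blinking ON phases.
    """

    max_value: int = 255
    interval: float = 0.1
    interval_low: float = 0.0
    brightness: int = 255

    def __post_init__(self) -> None:
        if not 0 <= self.max_value <= 255:
            raise ValueError("max_value must be a byte (0-255)")
        if not 0 <= self.brightness <= 255:
            raise ValueError("brightness must be a byte (0-255)")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.interval_low < 0:
            raise ValueError("interval_low must be non-negative")


@dataclass(frozen=True)
class StimulusTimeline:
    """Step-function light waveform: ``events`` are (time_s, value) change
    points, strictly increasing in time, starting at t = 0."""

    events: tuple

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("timeline needs at least one event")
        times = [t for t, _ in self.events]
        if times[0] != 0.0:
            raise ValueError("timeline must start at t = 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(not 0 <= v <= 255 for _, v in self.events):
            raise ValueError("event values must be bytes (0-255)")

    def value_at(self, t: float) -> int:
        """Latest event value at or before t; 0 before the first event."""
        v = 0
        for et, ev in self.events:
            if et <= t:
                v = ev
            else:
                break
        return v

    @property
    def duration(self) -> float:
        return self.events[-1][0]


@dataclass(frozen=True)
class LogRecord:
    host_time_s: float
    value: int


@dataclass(frozen=True)
class DriftModel:
    """Linear clock map ``device = slope * host + offset`` (seconds)."""

    offset: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def to_host(self, device_time: float) -> float:
        return (device_time - self.offset) / self.slope

    def to_device(self, host_time: float) -> float:
        return self.slope * host_time + self.offset


@dataclass(frozen=True)
class QuadraticFit:
    """y = a x² + b x + c with its coefficient of determination."""

    a: float
    b: float
    c: float
    r_squared: float


def intensity_ramp(params: ProtocolParams) -> StimulusTimeline:
    """Linear intensity ramp: value k at time k·interval for k = 0..max_value.

    The value-0 starting event is included, so the timeline has
    ``max_value + 1`` events and spans ``max_value * interval`` seconds.
    """
    events = tuple((k * params.interval, k) for k in range(params.max_value + 1))
    return StimulusTimeline(events)


def blinking(params: ProtocolParams, n_cycles: int) -> StimulusTimeline:
    """ON/OFF cycling at fixed brightness after an initial off period.

    Off on [0, interval_low), then alternating ON/OFF phases of
    ``interval`` seconds each, with ``n_cycles`` ON phases in total.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    events: list[tuple[float, int]] = [(0.0, 0)] if params.interval_low > 0 else []
    t = params.interval_low
    for _ in range(n_cycles):
        events.append((t, params.brightness))
        events.append((t + params.interval, 0))
        t += 2 * params.interval
    if events[0][0] != 0.0:  # interval_low == 0: first ON event is at t = 0
        events.insert(0, (0.0, 0))
    # de-duplicate t=0 when interval_low == 0 and the first ON replaces it
    if len(events) >= 2 and events[0][0] == events[1][0]:
        events.pop(0)
    return StimulusTimeline(tuple(events))


def moving_average(signal: Sequence[float], window: int) -> np.ndarray:
    """Causal (trailing) moving average; index i averages the last
    ``min(window, i + 1)`` samples.  Output length equals input length."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(signal, dtype=np.float64)
    if window == 1:
        return x.copy()
    csum = np.cumsum(x)
    out = np.empty_like(x)
    w = int(window)
    for i in range(len(x)):
        lo = max(0, i - w + 1)
        out[i] = (csum[i] - (csum[lo - 1] if lo > 0 else 0.0)) / (i - lo + 1)
    return out


def write_state_log(timeline: StimulusTimeline, drift: DriftModel = DriftModel(),
                    sample_period_s: float = 0.1, jitter_sd: float = 0.0,
                    seed: int = 0, duration_s: float | None = None) -> str:
    """Simulate the acquisition computer's timestamped state log.

    The controller reports its current value every ``sample_period_s``
    (device clock); each report is stamped with the host time
    ``(device - offset)/slope`` plus optional Gaussian jitter.  Returns
    CSV text with header ``timestamp,value``.
    """
    if sample_period_s <= 0:
        raise ValueError("sample_period_s must be positive")
    if duration_s is None:
        duration_s = timeline.duration
    n = int(math.floor(duration_s / sample_period_s)) + 1
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    lines = ["timestamp,value"]
    for k in range(n):
        dev_t = k * sample_period_s
        host_t = drift.to_host(dev_t)
        if jitter_sd > 0:
            host_t += rng.normal(0.0, jitter_sd)
        lines.append(f"{host_t:.9f},{timeline.value_at(dev_t)}")
    return "\n".join(lines) + "\n"


def parse_state_log(source) -> list[LogRecord]:
    """Parse a ``timestamp,value`` CSV (text, path, or file object)."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise ValueError("state log is empty (missing header)")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[:2] != ["timestamp", "value"]:
        raise ValueError(f"unexpected state-log header: {lines[0]!r}")
    records: list[LogRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            t = float(parts[0])
            v = int(float(parts[1]))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed state-log row at line {lineno}: {line!r}") from exc
        records.append(LogRecord(host_time_s=t, value=v))
    return records


def estimate_drift(device_times: Sequence[float],
                   host_times: Sequence[float]) -> DriftModel:
    """Least-squares fit of ``device = slope * host + offset``."""
    d = np.asarray(device_times, dtype=np.float64)
    h = np.asarray(host_times, dtype=np.float64)
    if d.shape != h.shape or d.ndim != 1 or len(d) < 2:
        raise ValueError("need >= 2 paired timestamps")
    if np.ptp(h) == 0 or np.ptp(d) == 0:
        raise ValueError("degenerate timestamps: no spread")
    slope, offset = np.polyfit(h, d, 1)
    return DriftModel(offset=float(offset), slope=float(slope))


def frame_states(frame_times: Sequence[float], records: Sequence[LogRecord],
                 drift: DriftModel | None = None) -> np.ndarray:
    """Stimulus value in force at each frame time.

    ``drift`` maps record timestamps onto the frame clock
    (``t_frame = drift.to_device(t_record)``); pass ``None`` when both are
    already on the same clock.  Each frame takes the value of the latest
    record at or before it; frames before the first record get 0.
    """
    if not len(records):
        raise ValueError("no log records")
    rt = np.array([r.host_time_s for r in records], dtype=np.float64)
    rv = np.array([r.value for r in records])
    if drift is not None:
        rt = drift.slope * rt + drift.offset
    order = np.argsort(rt, kind="stable")
    rt, rv = rt[order], rv[order]
    ft = np.asarray(frame_times, dtype=np.float64)
    idx = np.searchsorted(rt, ft, side="right") - 1
    out = np.where(idx >= 0, rv[np.clip(idx, 0, None)], 0)
    return out


def fit_quadratic(x_values: Sequence[float], y_values: Sequence[float]) -> QuadraticFit:
    """Least-squares quadratic ``y = a x² + b x + c`` with R².

    R² = 1 − SS_res/SS_tot, defined as 1 for a zero-variance target (a
    constant fitted perfectly by its own constant term).
    """
    x = np.asarray(x_values, dtype=np.float64)
    y = np.asarray(y_values, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values for a quadratic fit")
    a, b, c = np.polyfit(x, y, 2)
    resid = y - (a * x ** 2 + b * x + c)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return QuadraticFit(float(a), float(b), float(c), r2)


def apply_calibration(fit: QuadraticFit, x) -> np.ndarray | float:
    """Evaluate the calibration at sensor reading(s) x, clipped below at 0
    (negative irradiance is unphysical)."""
    arr = np.asarray(x, dtype=np.float64)
    y = np.clip(fit.a * arr ** 2 + fit.b * arr + fit.c, 0.0, None)
    return float(y) if np.isscalar(x) or arr.ndim == 0 else y
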