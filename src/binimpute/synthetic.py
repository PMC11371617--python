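"""Seeded generators for day-structured series with heart-rate-like and
power-like statistics.

The additive model per day ``d`` and clock slot ``t`` is::

    x[d, t] = m[t] + a[d] + drift[d, t] + burst[d, t] + eps[d, t]

with ``m`` a deterministic diurnal profile (cosine for heart-like, two-level
step for power-like), ``a[d] ~ N(0, day_offset_sd^2)`` a day-level offset,
``drift`` a smooth random-phase harmonic process independent across days,
``burst`` a sum of one-sided exponentially decaying kernels whose event
times form a Poisson process inside the active clock window, and ``eps``
i.i.d. Gaussian noise.  One RNG stream per day is derived from
``(seed, day)`` so adding days never perturbs earlier days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import SECONDS_PER_DAY, to_clock_seconds, to_timedelta
from .daygrid import DayGrid
from .errors import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "GeneratorTruth",
    "diurnal_mean",
    "generate_heart_like",
    "generate_power_like",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the additive day-structured generator.

    Defaults emulate 1-min heart-rate telemetry over 30 complete days with a
    quiet 3-4 a.m. stretch and an eventful 3-4 p.m. stretch.
    """

    n_days: int = 30
    step: pd.Timedelta = pd.Timedelta(minutes=1)
    baseline: float = 65.0
    circadian_amplitude: float = 10.0
    circadian_phase: str = "16:00"  # clock time of the diurnal peak
    day_offset_sd: float = 3.0
    noise_sd: float = 2.0
    active_window: tuple[str, str] = ("15:00", "16:00")
    active_burst_rate: float = 6.0  # events per hour inside the window
    active_burst_amplitude: float = 15.0
    active_burst_halflife: pd.Timedelta = pd.Timedelta(minutes=3)
    drift_sd: float = 0.0
    drift_harmonics: int = 3
    seed: int = 0
    start_date: _dt.date = _dt.date(2024, 1, 1)
    # power-like profile: high plateau inside day_window, low outside
    day_window: tuple[str, str] = ("07:00", "22:00")

    def __post_init__(self) -> None:
        object.__setattr__(self, "step", to_timedelta(self.step))
        object.__setattr__(
            self, "active_burst_halflife", to_timedelta(self.active_burst_halflife)
        )
        if self.n_days < 2:
            raise ConfigurationError("n_days must be >= 2")
        step_s = int(self.step.total_seconds())
        if SECONDS_PER_DAY % step_s != 0:
            raise ConfigurationError(f"step {self.step} does not divide 24 h")
        for name in ("day_offset_sd", "noise_sd", "drift_sd",
                     "circadian_amplitude", "active_burst_amplitude",
                     "active_burst_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def slots_per_day(self) -> int:
        return SECONDS_PER_DAY // int(self.step.total_seconds())

    @property
    def slot_seconds(self) -> np.ndarray:
        return np.arange(self.slots_per_day, dtype=np.int64) * int(
            self.step.total_seconds()
        )


@dataclass
class GeneratorTruth:
    """Ground-truth components stored alongside a generated grid."""

    day_offsets: np.ndarray  # a_d, length D
    slot_mean: np.ndarray  # m_t, length T
    burst_events: list[np.ndarray]  # per-day event times, seconds since midnight
    drifts: np.ndarray  # D x T smooth day-specific component


def diurnal_mean(config: SyntheticConfig, slot_seconds) -> np.ndarray:
    """Deterministic cosine profile: baseline + A*cos(2*pi*(t - phase)/24h)."""
    t = np.asarray(slot_seconds, dtype=float)
    phase = to_clock_seconds(config.circadian_phase)
    return config.baseline + config.circadian_amplitude * np.cos(
        2.0 * np.pi * (t - phase) / SECONDS_PER_DAY
    )


def _step_mean(config: SyntheticConfig, slot_seconds) -> np.ndarray:
    """Two-level profile: baseline plus amplitude inside the day window."""
    t = np.asarray(slot_seconds)
    lo = to_clock_seconds(config.day_window[0])
    hi = to_clock_seconds(config.day_window[1])
    return config.baseline + config.circadian_amplitude * (
        (t >= lo) & (t < hi)
    ).astype(float)


def _day_rng(config: SyntheticConfig, day: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(day,))
    )


def _burst_profile(config: SyntheticConfig, rng, amplitude: float):
    """Poisson events in the active window, one-sided 2^(-dt/halflife) decay."""
    lo = to_clock_seconds(config.active_window[0])
    hi = to_clock_seconds(config.active_window[1])
    hours = (hi - lo) / 3600.0
    n_events = rng.poisson(config.active_burst_rate * hours)
    events = np.sort(rng.uniform(lo, hi, size=n_events))
    t = config.slot_seconds.astype(float)
    profile = np.zeros_like(t)
    half_s = config.active_burst_halflife.total_seconds()
    for s in events:
        dt = t - s
        live = dt >= 0
        profile[live] += amplitude * np.exp2(-dt[live] / half_s)
    return profile, events


def _drift_profile(config: SyntheticConfig, rng) -> np.ndarray:
    """Smooth zero-mean within-day process, sd = drift_sd, iid across days."""
    t = config.slot_seconds.astype(float)
    if config.drift_sd == 0.0 or config.drift_harmonics < 1:
        rng.uniform(0, 2 * np.pi, size=max(config.drift_harmonics, 0))  # keep stream stable
        return np.zeros_like(t)
    phases = rng.uniform(0, 2 * np.pi, size=config.drift_harmonics)
    k = np.arange(1, config.drift_harmonics + 1)[:, None]
    waves = np.cos(2.0 * np.pi * k * t[None, :] / SECONDS_PER_DAY - phases[:, None])
    return config.drift_sd * np.sqrt(2.0 / config.drift_harmonics) * waves.sum(axis=0)


def _generate(config: SyntheticConfig, slot_mean: np.ndarray,
              burst_amplitude_per_day, truncate_at_zero: bool):
    d, t_cols = config.n_days, config.slots_per_day
    if burst_amplitude_per_day is None:
        burst_amp = np.full(d, config.active_burst_amplitude)
    else:
        burst_amp = np.asarray(burst_amplitude_per_day, dtype=float)
        if burst_amp.shape != (d,):
            raise ConfigurationError("burst_amplitude_per_day must have length n_days")

    values = np.empty((d, t_cols))
    offsets = np.empty(d)
    drifts = np.empty((d, t_cols))
    events: list[np.ndarray] = []
    for day in range(d):
        rng = _day_rng(config, day)
        offsets[day] = rng.normal(0.0, config.day_offset_sd)
        drifts[day] = _drift_profile(config, rng)
        burst, ev = _burst_profile(config, rng, burst_amp[day])
        events.append(ev)
        noise = rng.normal(0.0, config.noise_sd, size=t_cols)
        values[day] = slot_mean + offsets[day] + drifts[day] + burst + noise
    if truncate_at_zero:
        np.maximum(values, 0.0, out=values)

    day_labels = (
        np.datetime64(config.start_date) + np.arange(d)
    ).astype("datetime64[D]")
    grid = DayGrid(
        day_labels,
        config.slot_seconds,
        values,
        np.zeros((d, t_cols), dtype=bool),
        config.step,
    )
    truth = GeneratorTruth(offsets, slot_mean.copy(), events, drifts)
    return grid, truth


def generate_heart_like(
    config: SyntheticConfig | None = None,
    burst_amplitude_per_day=None,
) -> tuple[DayGrid, GeneratorTruth]:
    """Diurnal-cosine grid with day offsets, bursts, drift, and noise.

    ``burst_amplitude_per_day`` overrides the burst amplitude per day
    (same event times and noise as the unscaled run for a given seed).
    """
    config = config or SyntheticConfig()
    slot_mean = diurnal_mean(config, config.slot_seconds)
    return _generate(config, slot_mean, burst_amplitude_per_day, False)


def generate_power_like(
    config: SyntheticConfig | None = None,
    burst_amplitude_per_day=None,
) -> tuple[DayGrid, GeneratorTruth]:
    """Two-level step profile grid, values truncated below at zero."""
    if config is None:
        config = SyntheticConfig(
            baseline=0.4,
            circadian_amplitude=1.2,
            day_offset_sd=0.15,
            noise_sd=0.1,
            active_burst_amplitude=1.5,
            active_burst_rate=4.0,
        )
    slot_mean = _step_mean(config, config.slot_seconds)
    return _generate(config, slot_mean, burst_amplitude_per_day, True)
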