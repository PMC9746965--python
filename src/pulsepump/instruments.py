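"""Virtual measurement chain: liquid flow sensor and analytical balance.

The flow sensor resamples the true waveform at its own rate, optionally adds
Gaussian read noise, and saturates at its full-scale flow (65 ml/min for the
reference device).  The balance integrates the *true* output trace — the
gravimetric protocol is independent of the sensor — and reports collected
mass at 0.1 mg resolution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hydraulics import FlowTrace
from .profiles import HardwareConfig, ValidationError

__all__ = ["SensorReading", "CollectionResult", "sample_sensor", "collect_mass"]


@dataclass(frozen=True)
class SensorReading:
    """Flow-sensor output: uniform samples clipped to the sensor range."""

    sample_interval: float          # s
    values: np.ndarray              # ml/min, in [0, sensor_max_flow]
    noise_sd: float                 # ml/min
    seed: int | None
    origin: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.origin + np.arange(self.values.size) * self.sample_interval

    def to_csv(self, path, seed_header: bool = True) -> None:
        with open(path, "w") as fh:
            if seed_header and self.seed is not None:
                fh.write(f"# seed={self.seed}\n")
            fh.write("time_s,flow_ml_min\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6g},{v:.6g}\n")


def sample_sensor(trace: FlowTrace, hw: HardwareConfig,
                  noise_sd: float = 0.0,
                  seed: int | None = None) -> SensorReading:
    """Emulate the flow sensor reading a true waveform.

    Linear-interpolation resample at ``hw.sensor_sample_rate``, additive
    Gaussian noise (reproducible for a given seed), then clipping to
    [0, sensor_max_flow].  Trace bins are treated as point samples at their
    centres for interpolation.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd", "must be >= 0")
    dt = 1.0 / hw.sensor_sample_rate
    t_sensor = np.arange(trace.origin, trace.horizon, dt)
    centres = trace.times + trace.sample_interval / 2.0
    vals = np.interp(t_sensor, centres, trace.values)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
    vals = np.clip(vals, 0.0, hw.sensor_max_flow)
    return SensorReading(sample_interval=dt, values=vals, noise_sd=noise_sd,
                         seed=seed, origin=trace.origin)


@dataclass(frozen=True)
class CollectionResult:
    """One timed gravimetric collection from one channel."""

    scenario: str
    channel: int
    mass_g: float
    duration_min: float

    def __post_init__(self):
        if self.mass_g < 0:
            raise ValidationError("mass_g", "must be >= 0")

    def csv_row(self) -> str:
        return (f"{self.scenario},{self.channel},{self.mass_g:.4f},"
                f"{self.duration_min:g}")


def collect_mass(trace: FlowTrace, duration: float, hw: HardwareConfig,
                 scenario: str = "", channel: int = 0) -> CollectionResult:
    """Weigh the fluid collected over ``duration`` seconds of true flow.

    mass = fluid density x integral of the trace; rounded to 0.1 mg
    (analytical-balance resolution).
    """
    if duration > trace.horizon + trace.sample_interval / 2.0:
        raise ValidationError(
            "duration",
            f"{duration:g} s exceeds the trace horizon {trace.horizon:g} s")
    volume = trace.integral(trace.origin, trace.origin + duration)
    mass = round(hw.fluid_density * volume, 4)
    return CollectionResult(scenario=scenario, channel=channel,
                            mass_g=mass, duration_min=duration / 60.0)
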