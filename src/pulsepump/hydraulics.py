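"""Motion plan -> output flow waveform.

The plunger moves at constant velocity within each motion segment, so the
ideal output flow is piecewise constant (plunger velocity x barrel area,
negative during retraction).  The check valve at the channel output rectifies
the waveform (reverse flow refills the syringe instead of leaving the
channel), and the lumped tubing compliance damps it as a first-order
low-pass filter whose time constant is calibrated from the dampening factor.

Traces are uniformly sampled; sample ``i`` holds the average flow over the
bin ``[t0 + i*dt, t0 + (i+1)*dt)`` in ml/min, so ``sum(values) * dt / 60``
is the exact dispensed volume over the sampled span.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .motion import MotionPlan, build_schedule, quantize
from .profiles import (
    HardwareConfig,
    PumpProfile,
    SaturationWarning,
    ValidationError,
    periodic_damping_time_constant,
    pulse_amplitude,
)

__all__ = [
    "FlowTrace",
    "plan_to_ideal_flow",
    "rectify",
    "apply_damping",
    "simulate",
]


@dataclass(frozen=True)
class FlowTrace:
    """Uniformly sampled flow time series (ml/min, bin-averaged)."""

    sample_interval: float      # s
    values: np.ndarray          # ml/min
    origin: float = 0.0         # s, start of the first bin

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.sample_interval <= 0:
            raise ValidationError("sample_interval", "must be > 0")
        if vals.ndim != 1:
            raise ValidationError("values", "must be one-dimensional")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("values", "must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def horizon(self) -> float:
        """End time of the last bin, s."""
        return self.origin + self.values.size * self.sample_interval

    @property
    def times(self) -> np.ndarray:
        """Bin start times, s."""
        return self.origin + np.arange(self.values.size) * self.sample_interval

    def integral(self, t_start: float = None, t_end: float = None) -> float:
        """Dispensed volume (ml) over [t_start, t_end], partial bins
        included by linear proration."""
        t0 = self.origin if t_start is None else t_start
        t1 = self.horizon if t_end is None else t_end
        if t1 < t0:
            raise ValidationError("t_end", "must be >= t_start")
        dt = self.sample_interval
        edges = self.origin + np.arange(self.values.size + 1) * dt
        cum = np.concatenate(([0.0], np.cumsum(self.values) * dt / 60.0))
        v0, v1 = np.interp([t0, t1], edges, cum)
        return float(v1 - v0)

    def to_csv(self, path, seed: int | None = None) -> None:
        """Write ``time_s,flow_ml_min`` rows (6 significant digits)."""
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            fh.write("time_s,flow_ml_min\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6g},{v:.6g}\n")

    @classmethod
    def from_csv(cls, path) -> "FlowTrace":
        times, vals = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("time_s"):
                    continue
                t, v = line.split(",")
                times.append(float(t))
                vals.append(float(v))
        if len(times) < 2:
            raise ValidationError("trace", "need at least two samples")
        dt = times[1] - times[0]
        return cls(sample_interval=dt, values=np.array(vals), origin=times[0])


def plan_to_ideal_flow(plan: MotionPlan, hw: HardwareConfig,
                       sample_interval: float,
                       horizon: float | None = None) -> FlowTrace:
    """Sample the ideal (pre-valve) flow waveform of a motion plan.

    Flow is plunger velocity times barrel area, sign preserved (negative
    during retraction).  Bin-averaging is computed from the piecewise-linear
    cumulative-displacement curve, so the trace integral equals the net
    plunger displacement volume exactly.
    """
    fwd_durations = [s.duration for s in plan.segments if s.microsteps > 0]
    if fwd_durations and sample_interval > min(fwd_durations) / 20.0:
        raise ValidationError(
            "sample_interval",
            f"{sample_interval:g} s is too coarse: must be <= 1/20 of the "
            f"shortest systolic push ({min(fwd_durations):g} s)")
    end = plan.horizon if horizon is None else horizon
    n = max(int(math.ceil(end / sample_interval - 1e-9)), 0)
    if n == 0:
        return FlowTrace(sample_interval=sample_interval,
                         values=np.zeros(0))
    vpm = hw.volume_per_microstep
    # knots of the cumulative displaced-volume curve
    knot_t = [0.0]
    knot_v = [0.0]
    for seg in plan.segments:
        if seg.start > knot_t[-1]:
            knot_t.append(seg.start)
            knot_v.append(knot_v[-1])
        knot_t.append(seg.end)
        knot_v.append(knot_v[-1] + seg.microsteps * vpm)
    edges = np.arange(n + 1) * sample_interval
    cum = np.interp(edges, knot_t, knot_v)
    flow = np.diff(cum) / sample_interval * 60.0  # ml/s -> ml/min
    return FlowTrace(sample_interval=sample_interval, values=flow)


def rectify(trace: FlowTrace) -> FlowTrace:
    """Check-valve action: clamp reverse flow to zero samplewise."""
    return FlowTrace(sample_interval=trace.sample_interval,
                     values=np.maximum(trace.values, 0.0),
                     origin=trace.origin)


def apply_damping(trace: FlowTrace, tau: float) -> FlowTrace:
    """First-order exponential smoothing with time constant ``tau`` (s).

    Uses the exact zero-order-hold discretisation y[n] = a*y[n-1] +
    (1-a)*x[n] with a = exp(-dt/tau), which has unit DC gain (long-run
    volume preserved up to the filter tail).  tau = 0 is the identity.
    """
    if tau < 0:
        raise ValidationError("tau", "must be >= 0")
    if tau == 0 or trace.values.size == 0:
        return trace
    a = math.exp(-trace.sample_interval / tau)
    y = lfilter([1.0 - a], [1.0, -a], trace.values)
    return FlowTrace(sample_interval=trace.sample_interval, values=y,
                     origin=trace.origin)


def default_sample_interval(profile: PumpProfile) -> float:
    """Default trace resolution: systole_time / 50, floored at 1 ms."""
    return max(profile.systole_time / 50.0, 1e-3)


def simulate(profile: PumpProfile, hw: HardwareConfig,
             sample_interval: float | None = None) -> FlowTrace:
    """End-to-end waveform simulation for one channel.

    Pipeline: beat schedule -> microstep quantization -> ideal piecewise
    flow -> check-valve rectification -> compliance damping (time constant
    calibrated so the steady-state peak is attenuated by exactly the
    dampening factor).  Deterministic for fixed inputs.  The trace horizon
    covers the (possibly retraction-extended) schedule plus a filter tail.
    """
    if pulse_amplitude(profile) * profile.dampening_factor > hw.sensor_max_flow:
        warnings.warn(
            "undamped pulse amplitude "
            f"{pulse_amplitude(profile) * profile.dampening_factor:.3g} "
            f"ml/min exceeds the flow sensor range ({hw.sensor_max_flow:g} "
            "ml/min); sensor readings will saturate",
            SaturationWarning,
        )
    dt = default_sample_interval(profile) if sample_interval is None \
        else sample_interval
    tau = periodic_damping_time_constant(
        profile.systole_time, profile.beat_period, profile.dampening_factor)
    schedule = build_schedule(profile, hw)
    plan = quantize(schedule, hw)
    horizon = schedule.horizon + (7.0 * tau if tau > 0 else 0.0)
    trace = plan_to_ideal_flow(plan, hw, dt, horizon=horizon)
    trace = rectify(trace)
    return apply_damping(trace, tau)
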