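"""Pump profiles, hardware geometry, the amplitude model, and the organ-scenario library.

A pulsatile regime is commanded by five numbers: the bulk (time-averaged)
volume rate in ml/min, the beat rate in beats/min, the systolic time in
seconds (duration of the active push phase of each beat), a dimensionless
dampening factor representing the lumped compliance of the tubing system,
and the total flow duration.  The peak flow of a single pulsation follows

    amplitude [ml/min] = volume_rate * 60 / (systole_time * heart_rate * DF)

i.e. the per-beat bolus spread over the systolic interval and attenuated by
the compliance of the line.  The dampening factor is operationalised as the
peak-attenuation ratio of a first-order (single-compartment) low-pass
filter; :func:`damping_time_constant` gives the closed form for an isolated
rectangular pulse and :func:`periodic_damping_time_constant` the calibration
for a periodic pulse train, which matters once the inter-beat gap is no
longer long compared with the filter time constant.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources

import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ValidationError",
    "SaturationWarning",
    "ResolutionWarning",
    "PumpProfile",
    "HardwareConfig",
    "ScenarioTable",
    "pulse_amplitude",
    "damping_time_constant",
    "periodic_damping_time_constant",
    "load_profile",
    "load_hardware",
    "organ_scenarios",
]

# Verified operating envelope of the physical pump (rejected outside unless
# a profile is built with allow_unverified=True).
VERIFIED_RATE_RANGE = (0.01, 16.0)      # ml/min
VERIFIED_BEAT_RANGE = (1.0, 400.0)      # beats/min
VERIFIED_AMPLITUDE_RANGE = (0.02, 65.0)  # ml/min

#: pulses rendered with fewer microsteps than this cannot reproduce a
#: faithful per-beat waveform (the pump stays volumetrically correct).
MIN_FAITHFUL_MICROSTEPS = 8


class ValidationError(ValueError):
    """Raised when an input violates a physical or schema constraint.

    Carries the offending ``field`` name so command-line callers can name it.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class SaturationWarning(UserWarning):
    """Commanded amplitude exceeds the flow sensor's measurable range."""


class ResolutionWarning(UserWarning):
    """Per-beat bolus maps to too few microsteps for a faithful waveform."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(field_name, message)


def _num(value, field_name: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValidationError(field_name, f"expected a number, got {value!r}")
    if not math.isfinite(value):
        raise ValidationError(field_name, "must be finite")
    return float(value)


@dataclass(frozen=True)
class PumpProfile:
    """One channel's commanded pulsatile regime.

    ``allow_unverified`` relaxes the verified operating envelope (volume rate
    and beat rate bounds) for exploratory runs; physical consistency
    constraints (positivity, systole fitting within half a beat period,
    DF >= 1) are always enforced.
    """

    volume_rate: float          # ml/min, bulk output
    heart_rate: float           # beats/min
    systole_time: float         # s, active push per beat
    duration: float             # s, commanded flow time
    dampening_factor: float = 1.0
    label: str = ""
    allow_unverified: bool = field(default=False, compare=False)

    def __post_init__(self):
        vr = _num(self.volume_rate, "volume_rate")
        hr = _num(self.heart_rate, "heart_rate")
        st = _num(self.systole_time, "systole_time")
        du = _num(self.duration, "duration")
        df = _num(self.dampening_factor, "dampening_factor")
        _require(vr > 0, "volume_rate", "must be > 0")
        _require(hr > 0, "heart_rate", "must be > 0")
        _require(du > 0, "duration", "must be > 0")
        _require(df >= 1.0, "dampening_factor", "must be >= 1 (1 = undamped)")
        _require(st > 0, "systole_time", "must be > 0")
        # systolic push must fit within half a beat period
        half_period = 30.0 / hr
        _require(
            st <= half_period * (1 + 1e-12),
            "systole_time",
            f"must not exceed half the beat period ({half_period:.4g} s at "
            f"{hr:g} BPM)",
        )
        if not self.allow_unverified:
            lo, hi = VERIFIED_BEAT_RANGE
            _require(lo <= hr <= hi, "heart_rate",
                     f"outside verified pulsation range [{lo:g}, {hi:g}] BPM "
                     "(pass allow_unverified=True to override)")
            lo, hi = VERIFIED_RATE_RANGE
            _require(lo <= vr <= hi, "volume_rate",
                     f"outside verified output range [{lo:g}, {hi:g}] ml/min "
                     "(pass allow_unverified=True to override)")

    @property
    def beat_period(self) -> float:
        """Beat-to-beat interval, s."""
        return 60.0 / self.heart_rate


def pulse_amplitude(profile: PumpProfile) -> float:
    """Peak flow (ml/min) of a single pulsation for the commanded regime."""
    return (profile.volume_rate * 60.0
            / (profile.systole_time * profile.heart_rate
               * profile.dampening_factor))


def damping_time_constant(systole_time: float, dampening_factor: float) -> float:
    """Time constant (s) of the first-order compliance filter for an
    isolated rectangular pulse.

    Chosen so that a rectangular systolic pulse of duration ``systole_time``
    passed through a first-order low-pass filter with this time constant has
    its peak attenuated by exactly ``1/dampening_factor``:

        tau = -systole_time / ln(1 - 1/DF)       (DF > 1)

    DF = 1 means no compliance: tau = 0 (identity filter).
    """
    st = _num(systole_time, "systole_time")
    df = _num(dampening_factor, "dampening_factor")
    _require(st > 0, "systole_time", "must be > 0")
    _require(df >= 1.0, "dampening_factor", "must be >= 1")
    if df == 1.0:
        return 0.0
    return -st / math.log1p(-1.0 / df)


def periodic_damping_time_constant(systole_time: float, beat_period: float,
                                   dampening_factor: float) -> float:
    """Compliance filter time constant calibrated for a periodic pulse train.

    For a train of rectangular pulses (duration T, period P, height H) fed
    through a first-order filter, the steady-state peak is

        peak = H * (1 - b) / (1 - b*c),  b = exp(-T/tau), c = exp(-(P-T)/tau)

    because each pulse rides on the residual tail of its predecessors.  This
    solves for the tau that makes the steady-state peak exactly H/DF.  When
    the inter-beat gap is long compared with tau (c -> 0) this reduces to the
    isolated-pulse closed form of :func:`damping_time_constant`.

    An attenuation target below the conservation floor (H/DF < mean flow,
    i.e. DF >= P/T) is unreachable by any volume-conserving first-order
    filter; in that case a warning is issued and the isolated-pulse tau is
    returned as a best effort.
    """
    st = _num(systole_time, "systole_time")
    per = _num(beat_period, "beat_period")
    df = _num(dampening_factor, "dampening_factor")
    _require(st > 0, "systole_time", "must be > 0")
    _require(per > st, "beat_period", "must exceed the systole time")
    _require(df >= 1.0, "dampening_factor", "must be >= 1")
    if df == 1.0:
        return 0.0
    tau_single = damping_time_constant(st, df)
    if df >= per / st * (1 - 1e-9):
        warnings.warn(
            f"dampening factor {df:g} at duty cycle {st / per:.3g} targets a "
            "peak below the mean flow; no volume-conserving first-order "
            "filter can reach it. Using the isolated-pulse time constant.",
            SaturationWarning,
        )
        return tau_single

    def steady_gap(tau: float) -> float:
        b = math.exp(-st / tau)
        c = math.exp(-(per - st) / tau)
        return (1.0 - b) / (1.0 - b * c) - 1.0 / df

    lo = tau_single
    if steady_gap(lo) <= 0.0:
        return lo
    hi = lo
    for _ in range(200):
        hi *= 2.0
        if steady_gap(hi) < 0.0:
            break
    else:  # pragma: no cover - unreachable given the solvability guard
        return hi
    return float(brentq(steady_gap, lo, hi, rtol=1e-13))


@dataclass(frozen=True)
class HardwareConfig:
    """Geometry, drive-train and instrument constants of the physical pump.

    Defaults describe the reference build: five 3 ml syringes driven by
    200-step/rev steppers through 8 mm/rev lead screws at 16x microstepping,
    an ~8 s plunger retraction, and a 65 ml/min liquid flow sensor.
    """

    syringe_capacity: float = 3.0           # ml
    syringe_inner_diameter: float = 8.66    # mm (standard 3 ml barrel)
    lead_screw_pitch: float = 8.0           # mm/rev
    motor_full_steps_per_rev: int = 200
    microsteps: int = 16
    max_step_rate: float = 20000.0          # microsteps/s
    retraction_time: float = 8.0            # s
    channels: int = 5
    initial_fill_fraction: float = 1.0
    sensor_max_flow: float = 65.0           # ml/min
    sensor_sample_rate: float = 50.0        # Hz
    fluid_density: float = 1.0              # g/ml

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            _num(v, f.name)
            _require(v > 0, f.name, "must be > 0")
        _require(self.initial_fill_fraction <= 1.0, "initial_fill_fraction",
                 "must be in (0, 1]")
        _require(int(self.motor_full_steps_per_rev) == self.motor_full_steps_per_rev,
                 "motor_full_steps_per_rev", "must be an integer count")
        _require(int(self.microsteps) == self.microsteps,
                 "microsteps", "must be an integer count")

    @property
    def volume_per_microstep(self) -> float:
        """Dispensed volume per microstep, ml."""
        radius_cm = self.syringe_inner_diameter / 20.0
        area_cm2 = math.pi * radius_cm ** 2
        vol_per_rev = area_cm2 * self.lead_screw_pitch / 10.0  # ml/rev
        return vol_per_rev / (self.motor_full_steps_per_rev * self.microsteps)

    @property
    def travel_per_microstep(self) -> float:
        """Linear plunger travel per microstep, mm."""
        return self.lead_screw_pitch / (self.motor_full_steps_per_rev
                                        * self.microsteps)

    @property
    def usable_volume(self) -> float:
        """Dispensable volume per fill cycle, ml."""
        return self.initial_fill_fraction * self.syringe_capacity


_PROFILE_REQUIRED = ("volume_rate", "heart_rate", "systole_time", "duration")
_PROFILE_OPTIONAL = ("dampening_factor", "label", "allow_unverified")


def load_profile(path) -> PumpProfile:
    """Load and validate a pump profile from a JSON file."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError("profile", f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError("profile", "top-level JSON value must be an object")
    allowed = set(_PROFILE_REQUIRED) | set(_PROFILE_OPTIONAL)
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ValidationError(unknown[0], "unknown profile field")
    missing = [k for k in _PROFILE_REQUIRED if k not in raw]
    if missing:
        raise ValidationError(missing[0], "required profile field is missing")
    return PumpProfile(**raw)


def load_hardware(path) -> HardwareConfig:
    """Load a hardware configuration from JSON, applying defaults for
    omitted fields."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError("hardware", f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError("hardware", "top-level JSON value must be an object")
    allowed = {f.name for f in fields(HardwareConfig)}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ValidationError(unknown[0], "unknown hardware field")
    return HardwareConfig(**raw)


SCENARIO_COLUMNS = [
    "organ_system", "condition", "flow_rate_ml_min", "flow_sd_ml_min",
    "beat_rate_bpm", "systole_time_s", "ref",
]


@dataclass(frozen=True)
class ScenarioTable:
    """Battery of organ-system flow scenarios (one row per commanded regime).

    Columns: organ system, physiological condition, bulk flow rate (ml/min)
    with the source study's SD where reported, beat rate (BPM), systolic
    time (s), and a measurement-modality tag.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [c for c in SCENARIO_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(missing[0], "scenario table column missing")
        _require(len(df) >= 1, "scenario_table", "must contain at least one row")
        _require(bool((df.flow_rate_ml_min > 0).all()), "flow_rate_ml_min",
                 "all flow rates must be > 0")
        _require(bool(df.beat_rate_bpm.between(*VERIFIED_BEAT_RANGE).all()),
                 "beat_rate_bpm", "beat rates must lie in the verified range")
        _require(bool((df.systole_time_s > 0).all()), "systole_time_s",
                 "systolic times must be > 0")

    @classmethod
    def from_csv(cls, path) -> "ScenarioTable":
        return cls(pd.read_csv(path, comment="#"))

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return iter(self.frame.itertuples(index=False))

    def labels(self) -> list[str]:
        return [scenario_label(row) for row in self]

    def profile(self, row, duration: float,
                dampening_factor: float = 1.0) -> PumpProfile:
        """Build the pump profile commanded by one scenario row."""
        return PumpProfile(
            volume_rate=float(row.flow_rate_ml_min),
            heart_rate=float(row.beat_rate_bpm),
            systole_time=float(row.systole_time_s),
            duration=float(duration),
            dampening_factor=dampening_factor,
            label=scenario_label(row),
        )


def scenario_label(row) -> str:
    """Unique human-readable identifier for a scenario row."""
    return (f"{row.organ_system} | {row.condition} | "
            f"{row.flow_rate_ml_min:g} ml/min")


def organ_scenarios() -> ScenarioTable:
    """The packaged 19-row organ-system scenario battery.

    Spans human ocular, fingertip/skin, cerebral and rat splenic regimes with
    bulk flow rates whose study means +/- SD cover 0.025-16 ml/min.  Human
    scenarios default to 70 BPM / 0.1 s systole, rat scenarios to 380 BPM /
    0.054 s, except where the source study reported otherwise.
    """
    with resources.files("pulsepump.data").joinpath("scenarios.csv").open() as fh:
        table = ScenarioTable(pd.read_csv(fh))
    if len(table) != 19:  # packaged fixture contract
        raise ValidationError("scenario_table",
                              f"packaged battery must have 19 rows, "
                              f"found {len(table)}")
    return table
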