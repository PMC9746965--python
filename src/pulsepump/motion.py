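"""Beat scheduling, stepper quantization, and G-code export.

Compiles a commanded pulsatile regime into timed events: one systolic push
per beat at the beat period, with an automatic plunger retraction inserted
whenever the next push would overdraw the syringe.  Retraction pauses output
for ``retraction_time`` seconds while the check valves refill the barrel;
subsequent beats are shifted later so the pulse count and delivered volume
of the profile are preserved (the wall clock extends, inter-beat intervals
are never compressed).

Quantization converts each bolus to whole microsteps with an error-carrying
accumulator, so the cumulative rounding error never reaches one microstep.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

from .profiles import (
    MIN_FAITHFUL_MICROSTEPS,
    HardwareConfig,
    PumpProfile,
    ResolutionWarning,
    ValidationError,
)

__all__ = [
    "Pulse",
    "Retraction",
    "BeatSchedule",
    "MotionSegment",
    "MotionPlan",
    "per_beat_bolus",
    "build_schedule",
    "quantize",
    "export_gcode",
    "parse_gcode",
]

# absolute slack (ml) when testing syringe overdraw, so that a fill level
# reached exactly (up to float accumulation) does not trigger a retraction
_OVERDRAW_TOL = 1e-9


@dataclass(frozen=True)
class Pulse:
    """One systolic push: dispense ``bolus`` ml over ``systole_duration`` s."""
    start: float
    systole_duration: float
    bolus: float


@dataclass(frozen=True)
class Retraction:
    """Plunger return to its starting extension; output flow pauses."""
    start: float
    duration: float


@dataclass(frozen=True)
class BeatSchedule:
    """Time-ordered pulse/retraction events compiled from one profile."""

    events: tuple
    horizon: float          # s, end of the last beat cycle (wall clock)

    @property
    def pulses(self) -> list[Pulse]:
        return [e for e in self.events if isinstance(e, Pulse)]

    @property
    def retractions(self) -> list[Retraction]:
        return [e for e in self.events if isinstance(e, Retraction)]

    @property
    def total_volume(self) -> float:
        """Commanded dispense volume, ml."""
        return math.fsum(p.bolus for p in self.pulses)

    def validate(self, hw: HardwareConfig) -> None:
        """Check event ordering, non-overlap and per-cycle capacity."""
        t = -math.inf
        dispensed = 0.0
        for ev in self.events:
            if ev.start < t - 1e-12:
                raise ValidationError("events", "events overlap or are unordered")
            if isinstance(ev, Pulse):
                dispensed += ev.bolus
                if dispensed > hw.usable_volume + _OVERDRAW_TOL:
                    raise ValidationError(
                        "events", "cycle dispenses more than the usable volume")
                t = ev.start + ev.systole_duration
            else:
                dispensed = 0.0
                t = ev.start + ev.duration


def per_beat_bolus(profile: PumpProfile,
                   hw: HardwareConfig | None = None) -> float:
    """Volume dispensed per pulsation (ml/beat): volume_rate / heart_rate.

    When a hardware configuration is supplied, a :class:`ResolutionWarning`
    is issued if the bolus maps to fewer microsteps than needed for a
    faithful per-beat waveform (the plan still executes and remains
    volumetrically correct).
    """
    bolus = profile.volume_rate / profile.heart_rate
    if hw is not None:
        steps = bolus / hw.volume_per_microstep
        if steps < MIN_FAITHFUL_MICROSTEPS:
            warnings.warn(
                f"per-beat bolus {bolus * 1e3:.4g} ul is only {steps:.2g} "
                f"microsteps (< {MIN_FAITHFUL_MICROSTEPS}); the waveform "
                "cannot be rendered faithfully at this resolution",
                ResolutionWarning,
            )
    return bolus


def build_schedule(profile: PumpProfile, hw: HardwareConfig) -> BeatSchedule:
    """Compile a profile into its beat schedule with retraction catch-up.

    Pulses start at t = 0 and recur at the beat period; the pulse count is
    round(heart_rate * duration / 60).  Whenever the next bolus would
    overdraw the syringe a retraction of ``hw.retraction_time`` is inserted
    first and every later event shifts back by that amount, so the delivered
    volume and beat count are unaffected by refills.
    """
    bolus = profile.volume_rate / profile.heart_rate
    usable = hw.usable_volume
    if bolus > usable + _OVERDRAW_TOL:
        raise ValidationError(
            "volume_rate",
            f"single-beat bolus {bolus:.4g} ml exceeds the usable syringe "
            f"volume {usable:.4g} ml")
    n_pulses = math.floor(profile.heart_rate * profile.duration / 60.0 + 0.5)
    period = profile.beat_period
    events: list = []
    t = 0.0
    dispensed = 0.0
    pause = 0.0
    for _ in range(n_pulses):
        if dispensed + bolus > usable + _OVERDRAW_TOL:
            events.append(Retraction(start=t, duration=hw.retraction_time))
            t += hw.retraction_time
            pause += hw.retraction_time
            dispensed = 0.0
        events.append(Pulse(start=t, systole_duration=profile.systole_time,
                            bolus=bolus))
        dispensed += bolus
        t += period
    # wall clock: commanded flow time extended by every retraction pause
    horizon = max(profile.duration + pause, t)
    return BeatSchedule(events=tuple(events), horizon=horizon)


@dataclass(frozen=True)
class MotionSegment:
    """Constant-rate stepper move: ``microsteps`` (signed; negative =
    retraction) executed over ``duration`` seconds starting at ``start``."""
    start: float
    duration: float
    microsteps: int
    step_rate: float        # |microsteps| / duration, steps/s

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class MotionPlan:
    """Quantized stepper realisation of a beat schedule for one channel."""
    segments: tuple
    horizon: float
    channel: int = 0

    @property
    def forward_microsteps(self) -> int:
        return sum(s.microsteps for s in self.segments if s.microsteps > 0)

    def volume(self, hw: HardwareConfig) -> float:
        """Total forward dispense, ml."""
        return self.forward_microsteps * hw.volume_per_microstep


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def quantize(schedule: BeatSchedule, hw: HardwareConfig,
             channel: int = 0) -> MotionPlan:
    """Quantize a beat schedule into whole-microstep motion segments.

    Each bolus is rounded to whole microsteps (half away from zero) with the
    residual carried into the next pulse, bounding the cumulative error by
    one microstep.  Retractions become a single reverse segment undoing the
    forward travel accumulated since the previous refill.
    """
    vpm = hw.volume_per_microstep
    segments: list[MotionSegment] = []
    carry = 0.0
    fwd_since_refill = 0
    pulse_idx = 0
    for ev in schedule.events:
        if isinstance(ev, Pulse):
            ideal = ev.bolus / vpm + carry
            n = _round_half_away(ideal)
            carry = ideal - n
            if n > 0:
                rate = n / ev.systole_duration
                if rate > hw.max_step_rate:
                    raise ValidationError(
                        "max_step_rate",
                        f"pulse {pulse_idx} needs {rate:.0f} microsteps/s "
                        f"(> {hw.max_step_rate:g})")
                segments.append(MotionSegment(ev.start, ev.systole_duration,
                                              n, rate))
                fwd_since_refill += n
            pulse_idx += 1
        else:
            if fwd_since_refill > 0:
                rate = fwd_since_refill / ev.duration
                if rate > hw.max_step_rate:
                    raise ValidationError(
                        "max_step_rate",
                        f"retraction needs {rate:.0f} microsteps/s "
                        f"(> {hw.max_step_rate:g})")
                segments.append(MotionSegment(ev.start, ev.duration,
                                              -fwd_since_refill, rate))
                fwd_since_refill = 0
    return MotionPlan(segments=tuple(segments), horizon=schedule.horizon,
                      channel=channel)


# ---------------------------------------------------------------------------
# G-code-dialect export.  Grammar (relative positioning, one move per
# segment):
#   G91                      -- header: relative mode
#   G1 X<mm> F<mm/min> ; pulse <k> | retraction
#   G4 P<ms>                 -- dwell between moves
#   M2                       -- end of program
# ---------------------------------------------------------------------------

_GCODE_MOVE = re.compile(
    r"^G1 X(?P<x>-?\d+(?:\.\d+)?) F(?P<f>\d+(?:\.\d+)?)")
_GCODE_DWELL = re.compile(r"^G4 P(?P<ms>\d+(?:\.\d+)?)")


def export_gcode(plan: MotionPlan, hw: HardwareConfig) -> str:
    """Render a motion plan as a deterministic G-code-dialect text stream.

    Distances are plunger travel in mm (one microstep = lead screw pitch /
    steps per rev), feed rates in mm/min; idle intervals between segments
    become dwells so the stream is time-faithful.
    """
    tpm = hw.travel_per_microstep
    lines = [
        f"; pulsepump motion plan, channel {plan.channel}",
        "G91 ; relative positioning",
    ]
    t = 0.0
    pulse_idx = 0
    for seg in plan.segments:
        gap_ms = (seg.start - t) * 1000.0
        if gap_ms > 0.5:
            lines.append(f"G4 P{gap_ms:.1f}")
        dist = seg.microsteps * tpm
        feed = seg.step_rate * tpm * 60.0
        if seg.microsteps >= 0:
            tag = f"pulse {pulse_idx}"
            pulse_idx += 1
        else:
            tag = "retraction"
        lines.append(f"G1 X{dist:.4f} F{feed:.3f} ; {tag}")
        t = seg.end
    tail_ms = (plan.horizon - t) * 1000.0
    if tail_ms > 0.5:
        lines.append(f"G4 P{tail_ms:.1f}")
    lines.append("M2 ; end")
    return "\n".join(lines) + "\n"


def parse_gcode(text: str, hw: HardwareConfig) -> MotionPlan:
    """Parse a stream produced by :func:`export_gcode` back into a plan.

    Used for round-trip verification; segment volumes are reconstructed from
    the move distances, timings from feed rates and dwells.
    """
    tpm = hw.travel_per_microstep
    segments: list[MotionSegment] = []
    t = 0.0
    for line in text.splitlines():
        line = line.strip()
        m = _GCODE_MOVE.match(line)
        if m:
            dist = float(m.group("x"))
            feed = float(m.group("f"))
            steps = _round_half_away(dist / tpm)
            duration = abs(dist) / feed * 60.0 if feed > 0 else 0.0
            rate = abs(steps) / duration if duration > 0 else 0.0
            segments.append(MotionSegment(t, duration, steps, rate))
            t += duration
            continue
        m = _GCODE_DWELL.match(line)
        if m:
            t += float(m.group("ms")) / 1000.0
    return MotionPlan(segments=tuple(segments), horizon=t)
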