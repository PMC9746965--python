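"""Waveform metrics and the volumetric verification battery.

Reproduces the statistical protocol used to verify the pump: repeated timed
gravimetric collections per scenario, expected-vs-measured linear regression
with its ANOVA (overall and per flow-rate range), Bland-Altman agreement,
per-scenario absolute/relative SD, and global mean absolute / relative
error.  Waveform-side checks count beats (a beat counts only when its full
cycle completes inside the analysis window) and extract peak / mean /
trough / pulse-width metrics from simulated traces.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal import find_peaks

from .hydraulics import FlowTrace, simulate
from .instruments import collect_mass
from .profiles import (
    HardwareConfig,
    PumpProfile,
    ScenarioTable,
    ValidationError,
    periodic_damping_time_constant,
    pulse_amplitude,
    scenario_label,
)

__all__ = [
    "WaveformMetrics",
    "RegressionSummary",
    "AgreementSummary",
    "VerificationReport",
    "count_beats",
    "waveform_metrics",
    "ols_fit",
    "bland_altman",
    "scenario_stats",
    "run_verification",
]

#: flow-rate range boundaries, ml/min: low (0, 0.4], mid (0.4, 1.5], high above
DEFAULT_RANGE_BOUNDS = (0.4, 1.5)

#: default peak prominence for beat detection, as a fraction of the
#: commanded pulse amplitude
DEFAULT_PROMINENCE_FRACTION = 0.25


def count_beats(trace: FlowTrace, window: float, min_prominence: float,
                beat_period: float | None = None) -> int:
    """Count pulsation peaks in ``[0, window]`` seconds of a trace.

    Peaks are local maxima with prominence >= ``min_prominence``.  When
    ``beat_period`` is given, only beats whose full cycle completes inside
    the window are counted: the waveform onset (left edge of the peak or of
    its plateau) plus one beat period must not exceed the window.
    """
    if window > trace.horizon + trace.sample_interval / 2.0:
        raise ValidationError(
            "window", f"{window:g} s exceeds the trace horizon "
                      f"{trace.horizon:g} s")
    dt = trace.sample_interval
    n = int(round((window - trace.origin) / dt))
    x = trace.values[:n]
    if x.size < 3:
        return 0
    # a waveform whose total excursion is below the prominence threshold
    # has no countable beats (e.g. constant flow)
    if np.ptp(x) < min_prominence:
        return 0
    # snap near-identical samples together so floating-point jitter on a
    # plateau is not mistaken for many distinct peaks
    scale = float(np.max(np.abs(x))) or 1.0
    x = np.round(x / scale, 9) * scale
    # pad with rest flow so peaks touching either boundary are detectable
    distance = max(int(0.5 * beat_period / dt), 1) if beat_period else None
    padded = np.concatenate(([0.0], x, [0.0]))
    peaks, props = find_peaks(padded, prominence=min_prominence,
                              plateau_size=1, distance=distance)
    onsets = props["left_edges"] - 1          # undo padding offset
    # the waveform onset falls inside the (partial) bin before the first
    # plateau/peak sample; credit that bin when applying the cycle rule
    t_onset = trace.origin + (onsets - 1) * dt
    if beat_period is None:
        return int(peaks.size)
    complete = t_onset + beat_period <= window + dt / 2.0
    return int(np.count_nonzero(complete))


@dataclass(frozen=True)
class WaveformMetrics:
    """Per-trace pulsatility summary (all flows in ml/min, widths in s)."""

    beat_count: int
    peak_amplitude: float
    mean_flow: float
    trough_flow: float
    pulse_width: float


def waveform_metrics(trace: FlowTrace, profile: PumpProfile,
                     min_prominence: float | None = None) -> WaveformMetrics:
    """Extract pulsatility metrics from a simulated (retraction-free) trace.

    Peak and trough are the per-beat maxima/minima averaged over complete
    beats (beats inside the damping transient are excluded), mean flow is
    the average over the same whole beats, and pulse width is the time the
    phase-averaged beat spends above half its peak.
    """
    period = profile.beat_period
    dt = trace.sample_interval
    amp = pulse_amplitude(profile)
    if min_prominence is None:
        min_prominence = DEFAULT_PROMINENCE_FRACTION * amp
    total_beats = int(math.floor((trace.horizon - trace.origin) / period
                                 + 1e-9))
    # exclude any trailing filter-tail span that holds no pulse
    n_pulses = int(math.floor(profile.heart_rate * profile.duration / 60.0
                              + 0.5))
    total_beats = min(total_beats, n_pulses)
    if total_beats < 2:
        raise ValidationError("trace", "need at least 2 complete beats")
    tau = periodic_damping_time_constant(profile.systole_time, period,
                                         profile.dampening_factor)
    burn = int(math.ceil(7.0 * tau / period)) if tau > 0 else 0
    burn = min(burn, total_beats - 2)
    centres = trace.times + dt / 2.0
    # per-beat extrema over beats [burn, total_beats)
    bounds = trace.origin + np.arange(burn, total_beats + 1) * period
    idx = np.searchsorted(centres, bounds)
    peaks, troughs = [], []
    for i in range(len(idx) - 1):
        seg = trace.values[idx[i]:idx[i + 1]]
        if seg.size == 0:
            continue
        peaks.append(seg.max())
        troughs.append(seg.min())
    peak = float(np.mean(peaks))
    trough = float(np.mean(troughs))
    span = (total_beats - burn) * period
    mean_flow = trace.integral(bounds[0], bounds[-1]) / span * 60.0
    # phase-averaged beat on a common grid
    m = 256
    phase = np.arange(m) * period / m
    t_grid = (bounds[:-1][:, None] + phase[None, :]).ravel()
    folded = np.interp(t_grid, centres, trace.values).reshape(-1, m)
    avg_beat = folded.mean(axis=0)
    half = avg_beat.max() / 2.0
    pulse_width = float(np.count_nonzero(avg_beat >= half) * period / m)
    beats = count_beats(trace, window=trace.horizon,
                        min_prominence=min_prominence, beat_period=period)
    return WaveformMetrics(beat_count=beats, peak_amplitude=peak,
                           mean_flow=mean_flow, trough_flow=trough,
                           pulse_width=pulse_width)


@dataclass(frozen=True)
class RegressionSummary:
    """Expected-vs-measured least-squares fit with its ANOVA."""

    slope: float
    intercept: float            # ml/min
    r_squared: float
    f_stat: float
    p_value: float
    n: int


def ols_fit(expected, measured) -> RegressionSummary:
    """Ordinary least squares of measured on expected flow.

    R^2 = 1 - SSres/SStot; F and p come from the regression ANOVA with
    (1, n-2) degrees of freedom.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise ValidationError("measured", "length mismatch with expected")
    if x.size < 3:
        raise ValidationError("expected", "need at least 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("expected", "values must not all be equal")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionSummary(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        n=int(x.size),
    )


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman bias and 95% limits of agreement (ml/min)."""

    bias: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(expected, measured) -> AgreementSummary:
    """Agreement analysis: bias = mean(measured - expected), limits of
    agreement = bias +/- 1.96 * SD of the differences."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise ValidationError("measured", "length mismatch with expected")
    if x.size < 2:
        raise ValidationError("expected", "need at least 2 points")
    diffs = y - x
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementSummary(bias=bias, loa_low=bias - 1.96 * sd,
                            loa_high=bias + 1.96 * sd, n=int(x.size))


def scenario_stats(replicate_flows) -> tuple[float, float]:
    """Sample SD (ml/min) and relative SD (%) of replicate flow estimates."""
    x = np.asarray(replicate_flows, dtype=float)
    if x.size < 2:
        raise ValidationError("replicates", "need at least 2 replicates")
    mean = float(x.mean())
    if mean == 0:
        raise ValidationError("replicates", "mean flow must be nonzero")
    sd = float(x.std(ddof=1))
    return sd, 100.0 * sd / mean


@dataclass(frozen=True)
class VerificationReport:
    """Full output of the scenario verification battery."""

    readings: pd.DataFrame          # one row per scenario x replicate
    per_scenario: pd.DataFrame      # label, expected, mean, sd, rsd
    regressions: dict               # range name -> RegressionSummary | None
    agreements: dict                # range name -> AgreementSummary | None
    mae: float                      # ml/min
    mre: float                      # %
    seed: int
    replicates: int
    duration_min: float
    noise_sd: float
    dampening_factor: float

    def summary_dict(self) -> dict:
        return {
            "settings": {
                "seed": self.seed,
                "replicates": self.replicates,
                "duration_min": self.duration_min,
                "noise_sd": self.noise_sd,
                "dampening_factor": self.dampening_factor,
                "n_scenarios": int(self.per_scenario.shape[0]),
                "n_readings": int(self.readings.shape[0]),
            },
            "mae_ml_min": self.mae,
            "mre_percent": self.mre,
            "regressions": {k: (asdict(v) if v is not None else None)
                            for k, v in self.regressions.items()},
            "agreements": {k: (asdict(v) if v is not None else None)
                           for k, v in self.agreements.items()},
            "per_scenario": self.per_scenario.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
            fh.write("\n")

    def save(self, out_dir) -> None:
        """Write report.json plus flat CSV tables under ``out_dir``."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_json(out / "report.json")
        header = f"# seed={self.seed}\n"
        for name, frame in (("readings.csv", self.readings),
                            ("per_scenario.csv", self.per_scenario)):
            with open(out / name, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, index=False)

    def digest(self) -> str:
        lines = [
            f"{self.readings.shape[0]} readings across "
            f"{self.per_scenario.shape[0]} scenarios "
            f"({self.replicates} x {self.duration_min:g} min each)",
            f"MAE  {self.mae:.6f} ml/min",
            f"MRE  {self.mre:.6f} %",
        ]
        for name, reg in self.regressions.items():
            if reg is None:
                continue
            lines.append(
                f"{name:>5} range: R^2={reg.r_squared:.6f} "
                f"slope={reg.slope:.5f} intercept={reg.intercept:+.5f}")
        return "\n".join(lines)


def _range_name(flow: float, bounds: tuple[float, float]) -> str:
    low_cut, mid_cut = bounds
    if flow <= low_cut:
        return "low"
    if flow <= mid_cut:
        return "mid"
    return "high"


def run_verification(scenarios: ScenarioTable,
                     hw: HardwareConfig | None = None,
                     replicates: int = 10,
                     channels: int = 10,
                     duration_min: float = 10.0,
                     noise_sd: float = 0.0,
                     seed: int = 0,
                     dampening_factor: float = 1.0,
                     range_bounds: tuple[float, float] = DEFAULT_RANGE_BOUNDS,
                     sample_interval: float | None = None,
                     ) -> VerificationReport:
    """Run the gravimetric verification battery over a scenario table.

    Every scenario is simulated for ``duration_min`` minutes of commanded
    flow and collected ``replicates`` times (one beaker per channel).  When
    retractions extend the wall clock, collection waits for the profile to
    finish — the catch-up scheduler preserves total volume — and the flow
    estimate divides by the commanded flow time.  Flow estimates
    (mass / density / duration) are then compared against the commanded
    rates: full-range and per-range OLS + ANOVA, Bland-Altman, per-scenario
    SD/RSD, and global MAE / MRE.  Deterministic for a given seed.
    """
    if hw is None:
        hw = HardwareConfig()
    if replicates < 2:
        raise ValidationError("replicates", "need at least 2 replicates")
    duration_s = duration_min * 60.0
    rows = []
    for row in scenarios:
        label = scenario_label(row)
        profile = scenarios.profile(row, duration=duration_s,
                                    dampening_factor=dampening_factor)
        trace = simulate(profile, hw, sample_interval=sample_interval)
        # the schedule may extend past the commanded flow time (retraction
        # catch-up); weigh everything the profile delivers
        result = collect_mass(trace, trace.horizon, hw, scenario=label)
        measured = result.mass_g / hw.fluid_density / duration_min
        for rep in range(replicates):
            rows.append({
                "scenario": label,
                "organ_system": row.organ_system,
                "condition": row.condition,
                "expected_ml_min": float(row.flow_rate_ml_min),
                "replicate": rep,
                "channel": rep % channels,
                "mass_g": result.mass_g,
                "measured_ml_min": measured,
            })
    readings = pd.DataFrame(rows)
    per_rows = []
    for label, grp in readings.groupby("scenario", sort=False):
        sd, rsd = scenario_stats(grp.measured_ml_min.to_numpy())
        per_rows.append({
            "scenario": label,
            "expected_ml_min": float(grp.expected_ml_min.iloc[0]),
            "mean_measured_ml_min": float(grp.measured_ml_min.mean()),
            "sd_ml_min": sd,
            "rsd_percent": rsd,
            "n": int(grp.shape[0]),
        })
    per_scenario = pd.DataFrame(per_rows)

    expected = readings.expected_ml_min.to_numpy()
    measured = readings.measured_ml_min.to_numpy()
    abs_err = np.abs(measured - expected)
    mae = float(abs_err.mean())
    mre = float((100.0 * abs_err / expected).mean())

    ranges = np.array([_range_name(e, range_bounds) for e in expected])
    regressions: dict = {}
    agreements: dict = {}
    for name in ("full", "low", "mid", "high"):
        mask = np.ones_like(expected, dtype=bool) if name == "full" \
            else ranges == name
        xs, ys = expected[mask], measured[mask]
        if xs.size >= 3 and np.ptp(xs) > 0:
            regressions[name] = ols_fit(xs, ys)
        else:
            regressions[name] = None
        agreements[name] = bland_altman(xs, ys) if xs.size >= 2 else None

    return VerificationReport(
        readings=readings, per_scenario=per_scenario,
        regressions=regressions, agreements=agreements,
        mae=mae, mre=mre, seed=seed, replicates=replicates,
        duration_min=duration_min, noise_sd=noise_sd,
        dampening_factor=dampening_factor,
    )
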