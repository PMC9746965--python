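# Methods

## Scope and model

`pulsepump` is a deterministic digital twin of a reciprocating
positive-displacement syringe pump for pulsatile perfusion.  It models one
channel as a chain of idealized stages:

1. **Beat schedule.**  A regime (bulk rate `Q` ml/min, beat rate `HR` BPM,
   systolic time `T_sys` s, dampening factor `DF`, duration `D` s) compiles
   to `round(HR·D/60)` pulses starting at `t = 0` with period `60/HR`; each
   pulse dispenses the bolus `Q/HR` ml over `T_sys` at constant plunger
   velocity.  When the next bolus would overdraw the usable syringe volume
   (`initial_fill_fraction · syringe_capacity`), a retraction of
   `retraction_time` (default 8 s) is inserted and all later events shift
   back by that amount.  This *catch-up* rule preserves pulse count, beat
   spacing, and total volume exactly; only the wall clock extends.  We chose
   shifting over compressing inter-beat intervals because it preserves both
   beat frequency and bulk output simultaneously.
2. **Quantization.**  Boluses are converted to whole microsteps with an
   error-carrying accumulator (round half away from zero, signed carry), so
   the cumulative dispense error is below one microstep volume
   (`π·(d/2)²·pitch/(steps·µsteps)` ≈ 0.1473 µl at the defaults).  A pulse
   whose bolus resolves to fewer than 8 microsteps is flagged
   (`ResolutionWarning`) as unable to render a faithful per-beat waveform —
   at default hardware this boundary sits near 0.06 ml/min at 70 BPM — but
   still executes, because volumetric accuracy is unaffected.
3. **Hydraulics.**  Ideal flow is piecewise constant (velocity × barrel
   area, negative during retraction).  Traces are *bin-averaged* on a
   uniform grid, so the sampled integral equals the plunger displacement
   volume exactly.  The output check valve clamps reverse flow to zero
   samplewise.  Compliance is a single first-order low-pass filter applied
   with the exact zero-order-hold discretisation
   `y[n] = a·y[n−1] + (1−a)·x[n]`, `a = exp(−dt/τ)` (unit DC gain, volume
   conserving).
4. **Instruments.**  The flow sensor linearly resamples the trace at
   `sensor_sample_rate` (50 Hz default), optionally adds seeded Gaussian
   noise, and clips to `[0, sensor_max_flow]` (65 ml/min default).  The
   balance integrates the *true* trace — the gravimetric protocol does not
   depend on the sensor — times the fluid density (1 g/ml default), rounded
   to 0.1 mg.

## Dampening-factor semantics

`DF` is defined operationally: the peak of the damped waveform is the
undamped amplitude divided by `DF`.  For an isolated rectangular pulse this
fixes the filter time constant in closed form,
`τ = −T_sys/ln(1 − 1/DF)` (`damping_time_constant`).  For a periodic beat
train the residual exponential tail of each pulse raises the steady-state
peak above the single-pulse value, so `simulate` calibrates `τ` against the
periodic steady state instead (`periodic_damping_time_constant`): it solves

    (1 − b) / (1 − b·c) = 1/DF,   b = e^(−T_sys/τ),  c = e^(−(P−T_sys)/τ)

with `P` the beat period.  The two definitions agree whenever the diastolic
gap is long relative to `τ` (all 70 BPM regimes at moderate DF); the
periodic form is what keeps the peak-attenuation contract exact at fast
beat rates (e.g. 380 BPM rodent regimes), where the single-pulse constant
would overshoot the target peak by ~15% at DF = 2.  A target peak below the
mean flow (`DF ≥ P/T_sys`) is unreachable by any volume-conserving
first-order filter; the calibration then warns and falls back to the
single-pulse constant.  Whether the physical system's decay is
mono-exponential is not verifiable from the data the twin is built on; the
single-compartment filter is the simplest volume-conserving choice
consistent with the amplitude law.

## Parameter defaults

| parameter | default | rationale |
|---|---|---|
| syringe capacity | 3 ml | reference build |
| syringe inner diameter | 8.66 mm | standard 3 ml barrel |
| lead screw pitch | 8 mm/rev | common 3D-printer-class drive |
| motor steps / microstepping | 200 / 16× | typical stepper + driver |
| max step rate | 20 000 µsteps/s | supports peaks well past the 65 ml/min sensor range |
| retraction time | 8 s | measured refill pause of the reference build |
| initial fill fraction | 1.0 | full syringe at start; exposed because partially filled runs retract earlier |
| sensor full scale / rate | 65 ml/min, 50 Hz | liquid flow sensor class of the reference setup |
| balance resolution | 0.1 mg | analytical balance class |
| fluid density | 1 g/ml | degassed deionized water |
| trace sample interval | `T_sys/50`, ≥ 1 ms | ≥ 20 samples per systole required; 50 gives <0.2% peak error |
| beat-detection prominence | 25% of commanded amplitude | rejects quantization ripple, keeps damped peaks |

Profile validation enforces the verified operating envelope (1–400 BPM,
0.01–16 ml/min, systole ≤ half the beat period, DF ≥ 1); out-of-envelope
values require an explicit `allow_unverified` override.

## Scenario battery and verification statistics

The packaged 19-row scenario library (`organ_scenarios()`) encodes the
organ-system regimes the pump was verified against: human scenarios at
70 BPM / 0.1 s systole and rat splenic scenarios at 380 BPM / 0.054 s
unless the source study reported otherwise; bulk rates span 0.029–11 ml/min
(0.025–16 ml/min counting the studies' reported SDs).  All battery runs use
DF = 1, since no per-experiment compliance values are available.

`run_verification` performs, per scenario, `replicates` (default 10)
ten-minute gravimetric collections.  Collections integrate the full
(possibly retraction-extended) trace and divide by the commanded flow time,
mirroring a protocol that weighs after the profile completes; otherwise
high-flow scenarios (6–16 ml/min, which retract every ~20–30 s) would be
penalized for pauses the catch-up scheduler provably compensates.  The
statistics are: OLS of measured on expected flow with the regression ANOVA
(via statsmodels, cross-checked in tests against a normal-equations
oracle), computed over the full range and per flow range — low ≤ 0.4,
mid 0.4–1.5, high > 1.5 ml/min (the mid/high boundary is reported
inconsistently between 1.3 and 1.5 in the source material; 1.5 is used and
the split is configurable) — plus Bland–Altman bias and 1.96·SD limits of
agreement, per-scenario SD/RSD across replicates, and global MAE (ml/min)
and MRE (%).

Beat counting finds peaks by prominence and applies a *complete-cycle*
rule: a beat counts only if its waveform onset plus one beat period falls
inside the analysis window (resolution: one sample bin).  Waveform metrics
(peak, trough, mean, half-peak pulse width) average per-beat values over
whole beats after discarding a `7τ` damping transient; they assume a
retraction-free window, so callers analysing waveforms should keep the
analysis span inside one syringe fill.  With compliance enabled the visible
pulse (rise + decay) spreads to roughly twice the systole time, which is
reported through the pulse-width metric rather than enforced.

## What the twin does and does not show

The synthetic battery is noiseless by construction: replicates are
identical, and the only error sources are microstep quantization, the
0.1 mg balance rounding, and (for damped runs) the filter tail.  Its
agreement statistics (R² ≈ 1 − 2·10⁻⁹, MAE ≈ 6·10⁻⁵ ml/min) therefore
bound, rather than reproduce, a physical pump's figures — real hardware
adds motor/valve variability, tubing elasticity, evaporation, and sensor
noise that the twin models only as an optional Gaussian term on the sensor
(default SD 0, as no magnitude is documented).  Passing the battery shows
the *control computation* is volumetrically exact; it says nothing about
mechanical compliance drift or fluid-dynamic effects (inertia,
viscosity-dependent resistance, multi-compartment Windkessel behaviour are
all out of scope).

## Numerical choices

- Overdraw tests use a 1 ns-scale absolute slack (10⁻⁹ ml) so a syringe
  filled exactly by an integer number of boluses does not trigger a
  spurious retraction.
- Quantization ties round half away from zero; the signed carry makes any
  window of `N` beats accurate to `1/N` microstep on average.
- `τ` calibration brackets the root between the single-pulse constant and
  geometric doublings, solved with Brent's method to 10⁻¹³ relative
  tolerance.
- Peak detection snaps samples to 9 significant digits first; bin-averaged
  plateaus otherwise split into many float-jitter micro-peaks whose
  prominence bases reach the diastolic floor.
- G-code export writes relative moves at 0.1 µm resolution (one microstep
  = 2.5 µm of travel), dwells carry inter-beat timing; round-trip parsing
  reproduces every segment's microstep count exactly.
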