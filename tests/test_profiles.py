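"""Amplitude model, compliance calibration, validation, scenario library."""
import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsepump import (
    PumpProfile,
    SaturationWarning,
    ValidationError,
    damping_time_constant,
    load_hardware,
    load_profile,
    organ_scenarios,
    periodic_damping_time_constant,
    pulse_amplitude,
)


class TestPulseAmplitude:
    @pytest.mark.parametrize(
        "rate, bpm, systole, df, expected",
        [
            (1.0, 70, 0.1, 1.0, 8.5714),     # per-beat bolus over systole
            (0.6, 380, 0.054, 1.0, 1.7544),  # rat splenic inputs
            (1.0, 70, 0.1, 2.0, 4.2857),     # compliance halves the peak
        ],
    )
    def test_hand_values(self, rate, bpm, systole, df, expected):
        p = PumpProfile(volume_rate=rate, heart_rate=bpm, systole_time=systole,
                        duration=60, dampening_factor=df)
        assert pulse_amplitude(p) == pytest.approx(expected, abs=5e-5)

    @settings(derandomize=True, max_examples=50)
    @given(rate=st.floats(0.01, 16), k=st.floats(0.1, 10))
    def test_homogeneity_in_volume_rate(self, rate, k):
        """Scaling the volume rate scales the amplitude by the same factor."""
        base = PumpProfile(volume_rate=rate, heart_rate=70, systole_time=0.1,
                           duration=60)
        scaled = PumpProfile(volume_rate=rate * k, heart_rate=70,
                             systole_time=0.1, duration=60,
                             allow_unverified=True)
        assert pulse_amplitude(scaled) == pytest.approx(
            k * pulse_amplitude(base), rel=1e-12)

    def test_doubling_df_halves_amplitude(self):
        p1 = PumpProfile(volume_rate=2, heart_rate=80, systole_time=0.2,
                         duration=60, dampening_factor=1.5)
        p2 = PumpProfile(volume_rate=2, heart_rate=80, systole_time=0.2,
                         duration=60, dampening_factor=3.0)
        assert pulse_amplitude(p2) == pytest.approx(pulse_amplitude(p1) / 2,
                                                    rel=1e-12)


class TestDampingTimeConstant:
    def test_undamped_is_identity(self):
        assert damping_time_constant(0.1, 1.0) == 0.0

    def test_closed_form(self):
        assert damping_time_constant(0.1, 2.0) == pytest.approx(
            -0.1 / math.log(0.5), rel=1e-12)
        assert damping_time_constant(0.1, 2.0) == pytest.approx(0.14427,
                                                                abs=5e-6)

    def test_monotone_in_df(self):
        assert (damping_time_constant(0.1, 3.0)
                > damping_time_constant(0.1, 2.0) > 0)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValidationError, match="dampening_factor"):
            damping_time_constant(0.1, 0.5)


class TestPeriodicCalibration:
    def test_reduces_to_isolated_pulse_for_long_gaps(self):
        # beat period 100x the systole: the tail has fully decayed
        tau_iso = damping_time_constant(0.1, 2.0)
        tau_per = periodic_damping_time_constant(0.1, 10.0, 2.0)
        assert tau_per == pytest.approx(tau_iso, rel=1e-4)

    def test_exceeds_isolated_pulse_for_fast_beats(self):
        # at 380 BPM the residual tail raises the steady-state peak, so a
        # slower filter is needed to hit the same attenuation
        tau_iso = damping_time_constant(0.054, 2.0)
        tau_per = periodic_damping_time_constant(0.054, 60 / 380, 2.0)
        assert tau_per > tau_iso

    def test_steady_state_peak_hits_target(self):
        st_, per, df = 0.054, 60 / 380, 2.0
        tau = periodic_damping_time_constant(st_, per, df)
        b = math.exp(-st_ / tau)
        c = math.exp(-(per - st_) / tau)
        assert (1 - b) / (1 - b * c) == pytest.approx(1 / df, rel=1e-10)

    def test_unreachable_attenuation_warns(self):
        # duty cycle 1/2: a volume-conserving filter cannot attenuate the
        # peak below twice the mean
        with pytest.warns(SaturationWarning):
            periodic_damping_time_constant(0.5, 1.0, 5.0)


class TestProfileValidation:
    def test_heart_rate_above_verified_range_rejected(self):
        with pytest.raises(ValidationError, match="heart_rate"):
            PumpProfile(volume_rate=1, heart_rate=500, systole_time=0.05,
                        duration=60)

    def test_envelope_override(self):
        p = PumpProfile(volume_rate=1, heart_rate=500, systole_time=0.05,
                        duration=60, allow_unverified=True)
        assert p.heart_rate == 500

    def test_systole_exceeding_half_period_rejected(self):
        # at 70 BPM half a period is 30/70 = 0.4286 s
        with pytest.raises(ValidationError, match="systole_time"):
            PumpProfile(volume_rate=1, heart_rate=70, systole_time=0.5,
                        duration=60)

    @pytest.mark.parametrize("field, kwargs", [
        ("volume_rate", dict(volume_rate=-1)),
        ("duration", dict(duration=0)),
        ("dampening_factor", dict(dampening_factor=0.8)),
        ("systole_time", dict(systole_time=0)),
    ])
    def test_invalid_fields_name_the_field(self, field, kwargs):
        base = dict(volume_rate=1, heart_rate=70, systole_time=0.1,
                    duration=60)
        base.update(kwargs)
        with pytest.raises(ValidationError, match=field):
            PumpProfile(**base)


class TestJsonLoading:
    def test_minimal_profile_round_trip(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text(json.dumps({
            "volume_rate": 1, "heart_rate": 70, "systole_time": 0.1,
            "dampening_factor": 1, "duration": 600}))
        p = load_profile(path)
        assert p.volume_rate == 1 and p.dampening_factor == 1

    def test_missing_field_names_it(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text(json.dumps({"volume_rate": 1, "heart_rate": 70,
                                    "systole_time": 0.1}))
        with pytest.raises(ValidationError, match="duration"):
            load_profile(path)

    def test_ill_typed_field_rejected(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text(json.dumps({
            "volume_rate": "fast", "heart_rate": 70, "systole_time": 0.1,
            "duration": 600}))
        with pytest.raises(ValidationError, match="volume_rate"):
            load_profile(path)

    def test_hardware_defaults_applied(self, tmp_path):
        path = tmp_path / "hw.json"
        path.write_text(json.dumps({"syringe_capacity": 5}))
        hw = load_hardware(path)
        assert hw.syringe_capacity == 5
        assert hw.retraction_time == 8.0
        assert hw.sensor_max_flow == 65.0

    def test_unknown_hardware_field_rejected(self, tmp_path):
        path = tmp_path / "hw.json"
        path.write_text(json.dumps({"syringe_color": "blue"}))
        with pytest.raises(ValidationError, match="syringe_color"):
            load_hardware(path)


class TestHardwareGeometry:
    def test_volume_per_microstep(self, hw):
        # pi * (8.66/2 mm)^2 * 8 mm / (200 * 16) microsteps ~ 0.147 ul
        assert hw.volume_per_microstep * 1e3 == pytest.approx(0.1473,
                                                              abs=5e-4)

    def test_travel_per_microstep(self, hw):
        assert hw.travel_per_microstep == pytest.approx(0.0025, rel=1e-12)

    def test_nonpositive_dimension_rejected(self):
        from pulsepump import HardwareConfig
        with pytest.raises(ValidationError, match="lead_screw_pitch"):
            HardwareConfig(lead_screw_pitch=0)


class TestScenarioLibrary:
    def test_nineteen_rows(self):
        assert len(organ_scenarios()) == 19

    def test_fingertip_post_caffeine_row(self):
        rows = [r for r in organ_scenarios()
                if r.organ_system == "fingertip"
                and r.condition == "post-caffeine"]
        assert len(rows) == 1
        r = rows[0]
        assert (r.flow_rate_ml_min, r.beat_rate_bpm, r.systole_time_s) \
            == (0.029, 71, 0.1)

    def test_ophthalmic_artery_row(self):
        rows = [r for r in organ_scenarios()
                if r.organ_system == "ophthalmic artery"]
        assert len(rows) == 1
        r = rows[0]
        assert (r.flow_rate_ml_min, r.beat_rate_bpm, r.systole_time_s) \
            == (11, 70, 0.1)

    def test_flow_rates_span_study_envelope(self):
        """Study means +/- reported SD cover 0.025-16 ml/min."""
        frame = organ_scenarios().frame
        sd = frame.flow_sd_ml_min.fillna(0.0)
        assert (frame.flow_rate_ml_min - sd).min() == pytest.approx(0.025)
        assert (frame.flow_rate_ml_min + sd).max() == pytest.approx(16.0)

    def test_undamped_amplitudes_positive_and_bounded(self, hw):
        """Battery amplitudes stay within the verified 0.02-65 ml/min
        envelope except the ophthalmic artery row, which saturates the
        sensor by design."""
        table = organ_scenarios()
        amps = []
        for row in table:
            p = table.profile(row, duration=60.0)
            amps.append((row.organ_system, pulse_amplitude(p)))
        over = [o for o, a in amps if a > hw.sensor_max_flow]
        assert over == ["ophthalmic artery"]
        assert all(a >= 0.02 for _, a in amps)
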