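import pytest

from pulsepump import HardwareConfig, PumpProfile


@pytest.fixture(scope="session")
def hw():
    """Reference hardware build (3 ml syringes, 16x microstepping)."""
    return HardwareConfig()


@pytest.fixture(scope="session")
def big_syringe_hw():
    """Hardware with effectively unlimited syringe capacity (no retractions)."""
    return HardwareConfig(syringe_capacity=1000.0)


@pytest.fixture
def langham_profile():
    """Total pulsatile ocular flow via pneumotonometer: 1 ml/min at 70 BPM."""
    return PumpProfile(volume_rate=1.0, heart_rate=70.0, systole_time=0.1,
                       duration=600.0, label="ocular baseline")
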