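import pytest

from larvasense import electrostatics as es
from larvasense import synthetic as syn


@pytest.fixture
def quiet():
    """Noise-free noise model."""
    return syn.NoiseModel(white_sd=0.0, drift_amplitude=0.0)


@pytest.fixture
def short_cfg():
    """30 s recording at the reference 1 kHz rate."""
    return syn.RecordingConfig(duration=30.0, seed=11)


@pytest.fixture
def coarse_sim():
    """Fast electrostatic set-up: default geometry on a 5 um grid."""
    return dict(
        domain=es.SimDomain(grid_spacing=5.0),
        comb=es.CombGeometry(),
        larva=es.LarvaBody(),
        kin=es.MotionKinematics(),
        circuit=es.Circuit(),
    )
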