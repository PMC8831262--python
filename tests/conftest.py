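import numpy as np
import pytest

from shearhist import EffectSpec, generate_study
from shearhist.hemodynamics import FlowWaveform, FluidProperties, parametric_waveform


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture()
def steady_waveform():
    """Constant 5 ml/s flow."""
    return FlowWaveform(period=1.0, samples=np.full(32, 5.0))


@pytest.fixture()
def pulsatile_waveform():
    return parametric_waveform()


@pytest.fixture(scope="session")
def noise_free_study():
    """Small deterministic study: NC area driven by TAWSS tertile, no noise."""
    effects = [
        EffectSpec("nc", "tawss", (1.0, 1.0, 2.0)),
        EffectSpec("macrophage", "osi", (0.6, 0.4, 0.2)),
    ]
    return generate_study(2, 3, effects, seed=11)
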