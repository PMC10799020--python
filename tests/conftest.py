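import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from patchfrap import BeamProtocol, MobilityParams, NoiseModel


@pytest.fixture(scope="session")
def beam():
    """Acquisition matching the study's optics: w = 0.77 µm, ~68% bleach, 120 s recording."""
    return BeamProtocol(w=0.77, K=3.0, t_grid=np.arange(240) * 0.5, n_pre=10, monitor_interval=0.5)


@pytest.fixture(scope="session")
def mobility():
    """Receptor-like mobility: D a few 1e-2 µm²/s, mobile fraction ~65%."""
    return MobilityParams(D=0.03, R_f=0.65)


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseModel(scheme="signal-scaled", sigma0=0.02)
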