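import numpy as np
import pytest

from camovis.spectra import GRID_SIZE, ReflectanceSpectrum
from camovis.vision import ConeCatchVector, bluetit


@pytest.fixture(scope="session")
def viewer():
    return bluetit()


@pytest.fixture(scope="session")
def ideal_viewer():
    return bluetit("ideal")


def flat_spectrum(value: float, label: str = "") -> ReflectanceSpectrum:
    return ReflectanceSpectrum(np.full(GRID_SIZE, value), label=label)


def catches(q_uv, q_sw, q_mw, q_lw, q_dd=1.0, label="") -> ConeCatchVector:
    return ConeCatchVector(q_uv, q_sw, q_mw, q_lw, q_dd, label=label)
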