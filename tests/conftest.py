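import numpy as np
import pytest

from perivasc.pvsflow import PVSModel
from perivasc.synth import HypnogramSpec, StateBandParams, make_hypnogram


@pytest.fixture(scope="session")
def nrem_model():
    """Reference penetrating-arteriole PVS with NREM-like VLF oscillation."""
    return PVSModel(A_med=310.0, a_rel=0.1, period=5.0, R_ast=14.0)


@pytest.fixture(scope="session")
def still_model():
    """Same geometry with the oscillation switched off."""
    return PVSModel(A_med=310.0, a_rel=0.0, period=5.0, R_ast=14.0)


@pytest.fixture(scope="session")
def short_hypnogram():
    """One compressed sleep cycle for fast trace-level tests."""
    spec = HypnogramSpec(wbs_s=5, nrem_s=20, is_s=5, rem_s=8, was_s=5)
    return make_hypnogram(spec, seed=0)


@pytest.fixture(scope="session")
def default_params():
    return StateBandParams()


def section_variance(y: np.ndarray, cbar: np.ndarray) -> float:
    total = np.trapezoid(cbar, y)
    mu = np.trapezoid(cbar * y, y) / total
    return float(np.trapezoid(cbar * (y - mu) ** 2, y) / total)
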