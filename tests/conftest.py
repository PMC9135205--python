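import numpy as np
import pytest

from phagevolve import SimulationConfig, make_starting_genome
from phagevolve.targets import positive_control_architecture


@pytest.fixture
def start3():
    """Three-gene single-promoter starting genome."""
    return make_starting_genome(3)


@pytest.fixture
def control_arch():
    """Known three-gene architecture with promoters, terminators and an
    RNase site; the positive-control genotype."""
    return positive_control_architecture()


@pytest.fixture
def fast_sim():
    """Short-horizon simulator config for desk-scale evolutionary tests."""
    return SimulationConfig(horizon=100.0, sample_interval=5.0)


@pytest.fixture
def grid300():
    return np.linspace(0.0, 300.0, 61)
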