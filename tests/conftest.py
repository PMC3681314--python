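import numpy as np
import pytest

from rootflux.experiments import build_mechanism
from rootflux.layout import LayoutConfig, assign_pin_map, build_root_layout
from rootflux.tissue import TransportParams, build_system


@pytest.fixture(scope="session")
def small_reflux_system():
    """Desk-scale reflux system (1200 µm segment) shared across tests."""
    return build_mechanism("reflux_loop", LayoutConfig(segment_length=1200.0))


@pytest.fixture(scope="session")
def small_closed_system():
    """Closed conservative system (no influx, no decay) on a short segment."""
    lay = build_root_layout(LayoutConfig(segment_length=400.0))
    pmap = assign_pin_map(lay, "reflux_loop")
    return build_system(lay, pmap, TransportParams(d=0.0, J_in=0.0))


@pytest.fixture(scope="session")
def full_layout():
    return build_root_layout(LayoutConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
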