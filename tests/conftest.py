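import numpy as np
import pytest

from lymphoct.olag import lymphangiography
from lymphoct.omag import flow_volume
from lymphoct.phantom import default_spec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The default study phantom (seed 7): layered skin, three lymphatic
    lumens (one per standard dermal slab) and three blood vessels."""
    spec = default_spec()
    volume, truth = generate_phantom(spec, seed=7)
    return spec, volume, truth


@pytest.fixture(scope="session")
def default_flow(default_phantom):
    """Unsmoothed OMAG flow volume of the default phantom."""
    _, volume, _ = default_phantom
    return flow_volume(volume, mode="complex", register=True)


@pytest.fixture(scope="session")
def default_olag(default_phantom):
    """Full lymphangiography result on the default phantom."""
    _, volume, _ = default_phantom
    return lymphangiography(volume)
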