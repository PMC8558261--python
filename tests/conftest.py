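import math

import pytest

from taucable.cable_model import MembraneParams, compartmentalize
from taucable.morphology import BASAL, SOMA, Morphology, MorphPoint
from taucable.synthetic_data import load_presets, make_cylinder, sample_population

CANON = MembraneParams(Rm=10000.0, Cm=1.0, Ra=150.0)


def make_soma_only(radius: float = 5.0) -> Morphology:
    """Isopotential fixture: a soma sphere with a degenerate dendrite stub."""
    return Morphology(
        [
            MorphPoint(1, SOMA, 0.0, 0.0, 0.0, radius, -1),
            MorphPoint(2, BASAL, 0.0, 0.0, 0.0, 0.1, 1),
        ],
        name="soma_only",
    )


@pytest.fixture(scope="session")
def soma_model():
    """Single isopotential soma, r = 5 μm: R = Rm/A ≈ 3183 MΩ, τ = 10 ms."""
    return compartmentalize(make_soma_only(5.0), CANON)


@pytest.fixture(scope="session")
def cable_morph():
    """400 μm sealed cable, d = 1 μm, negligible soma."""
    return make_cylinder(1.0, 400.0, 81, soma_radius=0.01)


@pytest.fixture(scope="session")
def cable_model(cable_morph):
    return compartmentalize(cable_morph, CANON, max_len=5.0)


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def wt_tree(presets):
    return sample_population(presets["wt_like"], 1, 7)[0]


@pytest.fixture(scope="session")
def wt_tree_model(wt_tree):
    p = MembraneParams(Rm=35000.0, Cm=1.0, Ra=150.0, spine_density=1.25)
    return compartmentalize(wt_tree, p)
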