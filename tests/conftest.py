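import numpy as np
import pytest

from cytomap import synthetic


@pytest.fixture(scope="session")
def archetypes():
    return synthetic.default_archetypes()


@pytest.fixture(scope="session")
def two_area_spec(archetypes):
    """A straight two-archetype ribbon with a planted mid-arc border.

    Scaled-down study conditions used throughout the detection tests:
    2 mm cortical thickness, 3.6 mm arc, 6 μm pixels.
    """
    return synthetic.RibbonSpec(
        archetypes=(archetypes["granular"], archetypes["dysgranular_b"]),
        border_positions=(0.5,),
        geometry="straight",
        cortical_thickness=2000.0,
        arc_length=3600.0,
        pixel_size=6.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_area_section(two_area_spec):
    return synthetic.make_section(two_area_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
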