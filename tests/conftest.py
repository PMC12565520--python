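import pytest

import cwhto


@pytest.fixture(scope="session")
def prism():
    """60 x 45 x 100 mm rectangular prism phantom with its landmarks."""
    return cwhto.generate_prism_phantom(60.0, 45.0, 100.0)


@pytest.fixture(scope="session")
def tibia():
    """Default flared tibia phantom (70.8 mm plateau, MPTA 82.1)."""
    return cwhto.generate_parametric_tibia(cwhto.PhantomParams())


@pytest.fixture(scope="session")
def small_cohort():
    """Three synthetic knees at reduced mesh resolution (fast tests)."""
    return cwhto.generate_cohort(3, seed=11, n_ring=32, ring_spacing=3.0)
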