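import numpy as np
import pytest

import megmontage as mm


@pytest.fixture(scope="session")
def sphere():
    return mm.SphereModel()


@pytest.fixture(scope="session")
def helmet():
    """Full 306-channel synthetic helmet."""
    return mm.make_synthetic_helmet(seed=0)


@pytest.fixture(scope="session")
def br29(sphere):
    return mm.make_br29_locations(sphere)


@pytest.fixture(scope="session")
def leadfield(br29, helmet, sphere):
    return mm.build_leadfield(br29, helmet, sphere)


@pytest.fixture(scope="session")
def noise(helmet):
    return mm.NoiseModel.from_array(helmet)


@pytest.fixture(scope="session")
def tiny_helmet():
    """Small 24-channel helmet for cheap operator tests."""
    return mm.make_synthetic_helmet(n_sites=8, seed=1)


@pytest.fixture(scope="session")
def tiny_sources(sphere):
    """Four regional sources well inside the tiny helmet."""
    rng = np.random.default_rng(7)
    locs = []
    for i in range(4):
        v = rng.standard_normal(3)
        v[2] = abs(v[2]) + 0.5
        v /= np.linalg.norm(v)
        locs.append(mm.SourceLocation.at(f"L{i}", 0.06 * v, sphere))
    return mm.RegionalSourceSet(locations=locs, sphere=sphere)


@pytest.fixture(scope="session")
def tiny_leadfield(tiny_sources, tiny_helmet, sphere):
    return mm.build_leadfield(tiny_sources, tiny_helmet, sphere)
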