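import numpy as np
import pytest

from nlfep.fixtures import default_model, make_cycle_fixture
from nlfep.system import ParticleSystem, ThermoState


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def thermo300():
    return ThermoState(300.0)


@pytest.fixture(scope="session")
def cycle_fixture():
    return make_cycle_fixture(seed=1)


def random_system(n, box_length, seed, species="W", solute=()):
    """Random toy system with a floor on pair distances (no overlaps)."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box_length, size=(n, 3))
    # push apart any accidental near-overlaps deterministically
    for _ in range(200):
        from nlfep.system import minimum_image
        moved = False
        for a in range(n):
            delta = minimum_image(pos[a] - np.delete(pos, a, axis=0),
                                  np.full(3, box_length))
            r = np.linalg.norm(delta, axis=1)
            if r.min() < 2.2:
                pos[a] = rng.uniform(0, box_length, size=3)
                moved = True
        if not moved:
            break
    return ParticleSystem(
        positions=pos,
        species=np.array([species] * n, dtype=object),
        masses=np.full(n, 18.0),
        box=np.full(3, float(box_length)),
        solute_indices=frozenset(solute),
    )


@pytest.fixture()
def small_mixed_system():
    """20-atom mixed solute/solvent box for force tests."""
    sys_ = random_system(20, 11.0, seed=7)
    return ParticleSystem(
        positions=sys_.positions,
        species=np.array(["S"] * 4 + ["W"] * 16, dtype=object),
        masses=np.array([16.0] * 4 + [18.0] * 16),
        box=sys_.box,
        solute_indices=frozenset(range(4)),
    )
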