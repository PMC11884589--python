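import numpy as np
import pytest

from rpskit.calculators import MorseCluster, MorseClusterParams, MuellerBrown
from rpskit.toys import hydrogen_transfer_reactant, toy_water


#: explicit H2 Morse parameters for dimer-level tests (the default table keeps
#: H–H non-bonding inside molecules, so dimer tests pin their own well)
H2_PARAMS = {"D": 4.5, "a": 1.9, "r0": 0.74}


@pytest.fixture(scope="session")
def h2_morse() -> MorseCluster:
    p = H2_PARAMS
    return MorseCluster(
        MorseClusterParams({("H", "H"): (p["D"], p["a"], p["r0"])}), name="h2-morse"
    )


@pytest.fixture(scope="session")
def morse() -> MorseCluster:
    return MorseCluster()


@pytest.fixture(scope="session")
def mueller_brown() -> MuellerBrown:
    return MuellerBrown()


@pytest.fixture(scope="session")
def water(morse):
    return toy_water(morse)


@pytest.fixture(scope="session")
def ht_reactant(morse):
    """Minimized O–H···N hydrogen-transfer toy reactant."""
    return hydrogen_transfer_reactant(morse)


def random_geometry(rng: np.random.Generator, symbols, spread: float = 2.5,
                    min_separation: float = 1.0):
    """Well-separated random geometry (steep-repulsion regions avoided)."""
    from rpskit.core import Geometry

    while True:
        pos = rng.uniform(-spread, spread, size=(len(symbols), 3))
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        if len(symbols) == 1 or d[np.triu_indices(len(symbols), 1)].min() > min_separation:
            return Geometry.from_symbols(symbols, pos)
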