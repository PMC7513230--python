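import numpy as np
import pytest

from lmechem.networks import Reaction, ReactionNetwork, SpeciesSet, StateSpace


@pytest.fixture(scope="session")
def birth_death():
    """Linear birth-death network: 0 -> X at 10/s, X -> 0 at 1/s (mean 10)."""
    sp = SpeciesSet(("X",))
    return ReactionNetwork(sp, (Reaction((0,), (1,), 10.0), Reaction((1,), (0,), 1.0)))


@pytest.fixture(scope="session")
def bd_omega():
    return StateSpace((0,), (60,))


@pytest.fixture()
def rng():
    return np.random.default_rng(20180912)
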