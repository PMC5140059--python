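import numpy as np
import pytest

import reactionet as rn
from reactionet.network import ENZYMATIC_T_END, ENZYMATIC_T_START, ENZYMATIC_X0


@pytest.fixture(scope="session")
def enzymatic():
    return rn.fixture_network("enzymatic")


@pytest.fixture(scope="session")
def enzymatic_library(enzymatic):
    return rn.enumerate_candidates(enzymatic.species)


@pytest.fixture(scope="session")
def enzymatic_snapshots(enzymatic):
    """10^4-cell snapshot ensemble on the fixture's 13-point window."""
    t_grid = np.linspace(ENZYMATIC_T_START, ENZYMATIC_T_END, 13)
    return rn.ssa_simulate(enzymatic, ENZYMATIC_X0, t_grid, 10_000, seed=42)


@pytest.fixture(scope="session")
def death_network():
    """Single-species death process A -> 0 with unit rate."""
    sp = rn.make_species(["A"])
    return rn.ReactionNetwork(sp, [rn.Reaction((0,), (), 0, 1.0)])
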