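import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fluxprog.network_io import MetabolicNetwork, Metabolite, Reaction


@pytest.fixture
def toy_network():
    """4 reactions, 3 metabolites, 2 genes: EX_a -> a -> b -> biomass sink."""
    return MetabolicNetwork(
        metabolites=[Metabolite("a"), Metabolite("b"), Metabolite("c")],
        reactions=[
            Reaction("EX_a", {"a": -1.0}, lb=-10.0, ub=1000.0),
            Reaction("R_ab", {"a": -1.0, "b": 1.0}, lb=0.0, ub=5.0, gpr="g1"),
            Reaction("R_bc", {"b": -1.0, "c": 1.0}, lb=0.0, ub=1000.0, gpr="g2"),
            Reaction("biomass", {"c": -1.0}, lb=0.0, ub=1000.0),
        ],
        genes=["g1", "g2"],
        objective={"biomass": 1.0},
    )


@pytest.fixture
def loop_network():
    """Single free reversible loop: the 1-dimensional polytope v1 = v2."""
    return MetabolicNetwork(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("R1", {"A": -1.0, "B": 1.0}, lb=-2.0, ub=2.0),
            Reaction("R2", {"B": -1.0, "A": 1.0}, lb=-2.0, ub=2.0),
        ],
        objective={},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
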