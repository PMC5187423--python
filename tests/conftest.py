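import numpy as np
import pytest

from kinens.model_io import (MetabolicNetwork, Metabolite, Reaction,
                             Regulation)
from kinens.synthetic_fixtures import ToySpec, make_toy_model


def simple_network(reversible_chain: bool = False) -> MetabolicNetwork:
    """uptake -> A -> B -> biomass, single enzyme per step."""
    mets = [Metabolite("ext", boundary=True), Metabolite("A"),
            Metabolite("B")]
    rxns = [
        Reaction("upt", {"ext": -1, "A": 1}, exchange=True, lb=0, ub=10),
        Reaction("r1", {"A": -1, "B": 1}, enzymes=["E1"],
                 reversible=reversible_chain),
        Reaction("bm", {"B": -1}, exchange=True),
    ]
    return MetabolicNetwork(metabolites=mets, reactions=rxns,
                            biomass_id="bm", uptake_id="upt")


def uni_uni_network() -> MetabolicNetwork:
    """Clamped-boundary single catalysed reaction A -> B (for MM tests)."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [Reaction("v", {"A": -1, "B": 1}, enzymes=["E"])]
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


@pytest.fixture(scope="session")
def branched_model():
    return make_toy_model(ToySpec(preset="branched-14", seed=7))


@pytest.fixture(scope="session")
def linear_model():
    return make_toy_model(ToySpec(preset="linear-8", seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
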