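import numpy as np
import pytest

from rgem.model import MetabolicModel, Metabolite, Reaction
from rgem.synth import ToyNetworkSpec, build_redox_toy_model


@pytest.fixture(scope="session")
def toy_model():
    return build_redox_toy_model()


@pytest.fixture(scope="session")
def toy_model_no_ros():
    return build_redox_toy_model(ToyNetworkSpec(ros_branch=False))


@pytest.fixture()
def chain_model():
    """EX_A (uptake up to 10) -> R1: A->B -> DM_B (objective)."""
    mets = [Metabolite("A_c", compartment="c"), Metabolite("B_c", compartment="c")]
    rxns = [
        Reaction("EX_A", {"A_c": -1.0}, -10.0, 0.0),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
        Reaction("DM_B", {"B_c": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel(mets, rxns, objective_id="DM_B")


@pytest.fixture()
def parallel_model():
    """A->B through two alternative routes R1/R2; demand of 10."""
    mets = [Metabolite("A_c", compartment="c"), Metabolite("B_c", compartment="c")]
    rxns = [
        Reaction("EX_A", {"A_c": -1.0}, -10.0, 0.0),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, gpr="g1"),
        Reaction("R2", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, gpr="g2"),
        Reaction("DM_B", {"B_c": -1.0}, 0.0, 10.0),
    ]
    return MetabolicModel(mets, rxns, objective_id="DM_B")
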