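import pytest

import hillnet as hn

BASELINE = {"NE": 0.5, "FSK": 0.2, "IBMX": 0.2}


@pytest.fixture(scope="session")
def toy():
    return hn.builtin_model("toy")


@pytest.fixture(scope="session")
def betaAR():
    return hn.builtin_model("betaAR")


@pytest.fixture(scope="session")
def baseline_inputs():
    return dict(BASELINE)


@pytest.fixture(scope="session")
def betaAR_reference_matrix(betaAR, baseline_inputs):
    """Reference sensitivity matrix at the defaults (dP=-25%, n=1.4)."""
    return hn.sensitivity_matrix(betaAR, baseline_inputs, dP_frac=-0.25)


@pytest.fixture
def two_node_chain():
    return hn.NetworkModel(
        species=(hn.SpeciesSpec("A", "input"), hn.SpeciesSpec("B", "state")),
        reactions=(hn.make_reaction("A_B", "A => B"),),
        name="chain",
    )
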