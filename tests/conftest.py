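import numpy as np
import pytest

from gradedcat import (
    ItemBank,
    ItemParameters,
    SimulationDesign,
    generate_responses,
    promis_ue_bank,
)


@pytest.fixture(scope="session")
def ue_bank() -> ItemBank:
    """The 46-item upper-extremity reference bank."""
    return promis_ue_bank()


@pytest.fixture(scope="session")
def toy_bank() -> ItemBank:
    """Small 5-item bank with varied slopes and threshold placements."""
    items = [
        ItemParameters("t1", 1.2, (-1.5, -0.5, 0.5, 1.5)),
        ItemParameters("t2", 2.5, (-2.0, -1.0, 0.0, 1.0)),
        ItemParameters("t3", 0.8, (-0.5, 0.2, 0.9, 1.6)),
        ItemParameters("t4", 3.2, (-1.2, -0.8, -0.1, 0.7)),
        ItemParameters("t5", 1.8, (0.0, 0.6, 1.2, 2.0)),
    ]
    return ItemBank(items, label="toy bank")


@pytest.fixture(scope="session")
def cohort(ue_bank):
    """Single-group cohort of 2000 simulees from the reference bank,
    shared across tests that only read it."""
    matrix, thetas, groups = generate_responses(
        ue_bank, SimulationDesign(n_persons=2000, seed=7)
    )
    return matrix, thetas, groups


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
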