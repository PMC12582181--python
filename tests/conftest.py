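import pytest

from pritdose.nuclides import AC225, DecayChain, DecayStep, Nuclide, ac225_chain
from pritdose.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def chain() -> DecayChain:
    return ac225_chain()


@pytest.fixture(scope="session")
def ac225() -> Nuclide:
    return AC225


@pytest.fixture()
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=1234)


def make_single_alpha_chain(energy_mev: float = 5.0) -> DecayChain:
    """Minimal valid chain: one alpha step then a stable terminator."""
    parent = Nuclide("X-1", 10.0, "h")
    return DecayChain(
        parent=parent,
        steps=(
            DecayStep(parent, 1.0, energy_mev, position=0),
            DecayStep(Nuclide("X-0", 1e30, "d"), 1.0, 0.0, position=1, stable=True),
        ),
    )
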