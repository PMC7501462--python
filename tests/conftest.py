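import pytest

from ecswitch.gem_core import MetabolicModel, Metabolite, Reaction
from ecswitch.synthetic_data import ToyConfig, build_toy_gem, make_thermo_kcats


@pytest.fixture(scope="session")
def cfg0() -> ToyConfig:
    """Noise-free study configuration."""
    return ToyConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def toy_m145(cfg0):
    return build_toy_gem(cfg0, "M145")


@pytest.fixture(scope="session")
def toy_m1152(cfg0):
    return build_toy_gem(cfg0, "M1152")


@pytest.fixture(scope="session")
def toy_tables(cfg0, toy_m145):
    """(thermo, kcats, proteins) for the curated wild-type-like model."""
    return make_thermo_kcats(toy_m145, cfg0)


def build_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_A <- A -> B -> EX_B with all capacities 10."""
    m = MetabolicModel("chain")
    m.add_metabolite(Metabolite("A", compartment="c"))
    m.add_metabolite(Metabolite("B", compartment="c"))
    m.add_reaction(Reaction("EX_A", {"A": -1}, lower_bound=-uptake, upper_bound=0))
    m.add_reaction(Reaction("AB", {"A": -1, "B": 1}, lower_bound=0, upper_bound=10))
    m.add_reaction(Reaction("EX_B", {"B": -1}, lower_bound=0, upper_bound=10))
    m.objective = "EX_B"
    return m


@pytest.fixture()
def chain_model() -> MetabolicModel:
    return build_chain_model()
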