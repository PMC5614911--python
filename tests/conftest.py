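import pytest

from myomirnet.core import ReactionNetwork


@pytest.fixture
def birth_death() -> ReactionNetwork:
    """Linear birth-death chain: stationary law Poisson(a/b) = Poisson(100)."""
    net = ReactionNetwork("birth_death")
    net.add_species("X", 0)
    net.parameters.update({"a": 0.1, "b": 0.001})
    net.add_reaction("birth", [], ["X"], "a")
    net.add_reaction("death", ["X"], [], "b")
    return net


@pytest.fixture
def pure_decay() -> ReactionNetwork:
    """X -> 0 at k=1e-5 from X0=1000: closed form X0*exp(-k t)."""
    net = ReactionNetwork("decay")
    net.add_species("X", 1000)
    net.parameters["k"] = 1e-5
    net.add_reaction("decay", ["X"], [], "k")
    return net


@pytest.fixture
def gene_toggle() -> ReactionNetwork:
    """Single gene flipping between free and bound at symmetric rates."""
    net = ReactionNetwork("gene_toggle")
    net.add_species("G", 1, gene_state=True)
    net.add_species("G_bound", 0, gene_state=True)
    net.parameters.update({"k_on": 1e-3, "k_off": 1e-3})
    net.add_reaction("bind", ["G"], ["G_bound"], "k_on")
    net.add_reaction("unbind", ["G_bound"], ["G"], "k_off")
    net.add_conserved("G", "G_bound")
    return net


@pytest.fixture
def frozen_network(birth_death) -> ReactionNetwork:
    """All rate constants zero: every state is absorbing."""
    net = birth_death.copy()
    net.parameters.update({"a": 0.0, "b": 0.0})
    sp = net.species[0]
    net.species[0] = type(sp)(sp.id, sp.description, 42, sp.is_gene_state)
    return net


@pytest.fixture(scope="session")
def all_model_keys():
    return ("mir1", "mir181", "mir378", "mir143", "integrated")
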