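import hypothesis
import numpy as np
import pytest

from mirnet.network import InteractionNetwork

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def path_net() -> InteractionNetwork:
    """Path graph a-b-c."""
    return InteractionNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def star_net() -> InteractionNetwork:
    """Star with center s and leaves l1..l4."""
    return InteractionNetwork.from_edges([("s", f"l{i}") for i in range(1, 5)])


def random_connected_net(n: int, p: float, seed: int) -> InteractionNetwork:
    """Erdos-Renyi graph restricted to its largest component."""
    import networkx as nx

    from mirnet.network import largest_component

    g = nx.gnp_random_graph(n, p, seed=seed)
    net = InteractionNetwork.from_edges(
        ((f"g{u:04d}", f"g{v:04d}") for u, v in g.edges()),
        nodes=(f"g{u:04d}" for u in g.nodes()),
    )
    return largest_component(net)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
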