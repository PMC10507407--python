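import pytest

from osteonet.network_io import InteractionNetwork


def build_net(edges, nodes=(), score=0.95):
    """Small-graph builder: edges as (a, b) or (a, b, score) tuples."""
    net = InteractionNetwork()
    for v in nodes:
        net.add_node(v)
    for e in edges:
        a, b, *s = e
        net.add_edge(a, b, s[0] if s else score)
    return net


@pytest.fixture
def triangle():
    return build_net([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return build_net([("A", "B"), ("B", "C")])


@pytest.fixture
def star4():
    """Star: center c with 3 leaves."""
    return build_net([("c", "l1"), ("c", "l2"), ("c", "l3")])


def cycle(n):
    labels = [f"v{i}" for i in range(n)]
    return build_net([(labels[i], labels[(i + 1) % n]) for i in range(n)])


def complete(n):
    labels = [f"v{i}" for i in range(n)]
    return build_net(
        [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]
    )
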