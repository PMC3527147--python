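import numpy as np
import pytest

from netpolarity.network import network_from_edges


@pytest.fixture
def chain():
    """A -> B -> C."""
    return network_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_digraph(rng, max_nodes=50, p_edge=0.08, allow_self_loops=True):
    """A random directed graph as an edge set over integer-named genes."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if (i != j or allow_self_loops) and rng.random() < p_edge:
                edges.append((nodes[i], nodes[j]))
    return network_from_edges(edges, nodes=nodes)


def brute_force_reachable(network, gene):
    """Independent DFS oracle: genes reachable via paths of length >= 1."""
    succ = {}
    for (s, t) in network.edges:
        succ.setdefault(s, set()).add(t)
    seen = set()
    stack = list(succ.get(gene, ()))
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        stack.extend(succ.get(x, ()))
    return seen
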