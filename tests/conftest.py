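import pytest

from phenomod.core import InteractionNetwork, Ontology


def make_ontology(edges: dict[str, list[str]], root: str = "root") -> Ontology:
    """Build an Ontology from {term: [parents]} (root added automatically)."""
    terms = {root: ("root", frozenset())}
    for t, parents in edges.items():
        terms[t] = (t, frozenset(parents))
    return Ontology(terms, root=root)


def make_network(edges, nodes=()) -> InteractionNetwork:
    net = InteractionNetwork()
    for n in nodes:
        net.add_node(n)
    for e in edges:
        a, b = e[0], e[1]
        tags = e[2] if len(e) > 2 else {"ppi_hprd"}
        net.add_node(a)
        net.add_node(b)
        net.add_edge(a, b, tags)
    return net


@pytest.fixture
def chain_ontology():
    # root <- A <- B
    return make_ontology({"A": ["root"], "B": ["A"]})


@pytest.fixture
def diamond_ontology():
    # B reaches D by a length-2 path (via A) and a length-3 path (via C1,C2)
    return make_ontology(
        {
            "D": ["root"],
            "A": ["D"],
            "C2": ["D"],
            "C1": ["C2"],
            "B": ["A", "C1"],
        }
    )
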