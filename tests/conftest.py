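import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from mcnet import ScaffoldInteractome

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_scaffold(edges, nodes=()) -> ScaffoldInteractome:
    """Build a small in-memory scaffold from plain edge tuples."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        u, v = e[:2]
        ev = frozenset(e[2].split(";")) if len(e) > 2 else frozenset()
        g.add_edge(u, v, evidence=ev)
    return ScaffoldInteractome(g)


@pytest.fixture
def tiny_scaffold():
    # a-c edge plus a path a-x-b through a non-member hub
    return make_scaffold([("a", "x"), ("x", "b"), ("a", "c")])


@pytest.fixture(scope="session")
def small_benchmark():
    """A desk-size benchmark shared by the slower integration tests."""
    from mcnet import SynthSpec, generate_benchmark_collection

    spec = SynthSpec(
        n_nodes=400,
        mean_degree=6,
        module_size=15,
        internal_density=0.4,
        n_modules_per_class=5,
        n_linker_modules=1,
        seed=7,
    )
    return generate_benchmark_collection(spec)
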