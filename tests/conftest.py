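import numpy as np
import pytest

import fabrynet as fn


@pytest.fixture(scope="session")
def demo_graph():
    return fn.generate_network(fn.demo_small_config(seed=11))


@pytest.fixture(scope="session")
def demo_definition(demo_graph):
    cfg = fn.demo_small_config(seed=11)
    defn = fn.generate_disease_definition(demo_graph, cfg)
    from fabrynet.synthetic import align_directions

    return align_directions(demo_graph, defn)


@pytest.fixture(scope="session")
def demo_ensemble(demo_graph, demo_definition):
    return fn.sample_solutions(
        demo_graph,
        demo_definition,
        {demo_definition.anchor_stimulus: -1.0},
        50,
        seed=23,
        cfg=fn.PropagationConfig(acceptance_fraction=0.0),
    )


@pytest.fixture
def chain_graph():
    """A -> B -> C -> D directed chain, all positive."""
    g = fn.InteractomeGraph()
    for s, t in (("A", "B"), ("B", "C"), ("C", "D")):
        g.add_interaction(fn.Interaction(source=s, target=t, sign=+1, directed=True))
    return g


def random_graph(seed, n_nodes=None, p_edge=0.3, p_directed=0.5, p_negative=0.3):
    """Small random mixed-direction signed graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = n_nodes or int(rng.integers(2, 13))
    g = fn.InteractomeGraph()
    names = [chr(ord("a") + i) for i in range(n)]
    for nm in names:
        g.add_protein(fn.Protein(id=nm, gene_symbol=nm))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                g.add_interaction(
                    fn.Interaction(
                        source=names[i],
                        target=names[j],
                        sign=-1 if rng.random() < p_negative else +1,
                        directed=bool(rng.random() < p_directed),
                    )
                )
    return g
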