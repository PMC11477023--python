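import numpy as np
import pytest

import fabrynet as fn
from fabrynet.errors import SamplerFailureError, ValidationError
from fabrynet.propagation import MODULATION_EPSILON

from conftest import random_graph


def hand_propagate(graph, weights, stimulus, damping, transfer, max_depth=3):
    """Independent oracle: dict-based synchronous sweeps of the update rule."""
    arcs = []
    for ei, e in enumerate(graph.interactions):
        arcs.append((e.source, e.target, weights[ei]))
        if not e.directed:
            arcs.append((e.target, e.source, weights[ei]))
    # breadth limit
    frontier, reachable = set(stimulus), set(stimulus)
    for _ in range(max_depth):
        nxt = {b for a, b, _ in arcs if a in frontier}
        frontier = nxt - reachable
        reachable |= nxt
    act = {p: 0.0 for p in graph.proteins}
    act.update(stimulus)
    for _ in range(100):
        new = {}
        for p in graph.proteins:
            if p in stimulus:
                new[p] = stimulus[p]
            elif p not in reachable:
                new[p] = 0.0
            else:
                total = damping * sum(w * act[a] for a, b, w in arcs if b == p)
                new[p] = np.tanh(total) if transfer == "tanh" else float(
                    np.clip(total, -1, 1)
                )
        if max(abs(new[p] - act[p]) for p in act) < 1e-12:
            act = new
            break
        act = new
    return act


class TestPropagate:
    def test_zero_stimulus_gives_zero_activities(self, chain_graph):
        acts = fn.propagate(chain_graph, [1.0, 1.0, 1.0], {"A": 0.0})
        assert all(v == 0.0 for v in acts.values())

    def test_chain_transports_sign(self, chain_graph):
        cfg = fn.PropagationConfig(damping=1.0, transfer="clip-linear")
        acts = fn.propagate(chain_graph, [1.0, 1.0, 1.0], {"A": 1.0}, cfg)
        assert acts["B"] == pytest.approx(1.0)
        acts = fn.propagate(chain_graph, [-1.0, 1.0, 1.0], {"A": 1.0}, cfg)
        assert acts["B"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("transfer", ["tanh", "clip-linear"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_hand_iterated_oracle(self, seed, transfer):
        g = random_graph(seed, n_nodes=6, p_edge=0.5)
        rng = np.random.default_rng(seed + 100)
        weights = (rng.uniform(0.1, 1.0, size=g.n_interactions)
                   * [e.sign for e in g.interactions])
        stim = {list(g.proteins)[0]: 1.0}
        cfg = fn.PropagationConfig(damping=0.9, transfer=transfer)
        got = fn.propagate(g, weights, stim, cfg)
        expected = hand_propagate(g, weights, stim, 0.9, transfer)
        for p in g.proteins:
            assert got[p] == pytest.approx(expected[p], abs=1e-12)

    @pytest.mark.parametrize("transfer", ["tanh", "clip-linear"])
    def test_activities_bounded(self, transfer):
        g = random_graph(seed=8, n_nodes=12, p_edge=0.6)
        weights = [5.0 * e.sign for e in g.interactions]  # strong weights
        cfg = fn.PropagationConfig(damping=1.0, transfer=transfer)
        acts = fn.propagate(g, weights, {list(g.proteins)[0]: 1.0}, cfg)
        assert all(abs(v) <= 1.0 for v in acts.values())

    def test_nonfinite_weight_rejected(self, chain_graph):
        with pytest.raises(ValidationError):
            fn.propagate(chain_graph, [np.nan, 1.0, 1.0], {"A": 1.0})

    def test_unknown_stimulus_rejected(self, chain_graph):
        with pytest.raises(ValidationError):
            fn.propagate(chain_graph, [1.0, 1.0, 1.0], {"Z": 1.0})

    def test_unreached_nodes_stay_exactly_zero(self, chain_graph):
        cfg = fn.PropagationConfig(max_depth=1)
        acts = fn.propagate(chain_graph, [1.0, 1.0, 1.0], {"A": 1.0}, cfg)
        assert acts["C"] == 0.0 and acts["D"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_stimulus_on_positive_dags(self, seed):
        """Raising a clamp value never lowers any downstream activity."""
        rng = np.random.default_rng(seed)
        g = fn.InteractomeGraph()
        n = 8
        names = [f"n{i}" for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    g.add_interaction(
                        fn.Interaction(source=names[i], target=names[j],
                                       sign=+1, directed=True)
                    )
        for p in names:
            g.add_protein(fn.Protein(id=p, gene_symbol=p))
        weights = list(rng.uniform(0.1, 1.0, size=g.n_interactions))
        lo = fn.propagate(g, weights, {names[0]: 0.3})
        hi = fn.propagate(g, weights, {names[0]: 0.8})
        for p in names[1:]:
            assert hi[p] >= lo[p] - 1e-12


class TestSampler:
    def test_zero_acceptance_accepts_first_draws(self, demo_graph, demo_definition):
        ens = fn.sample_solutions(
            demo_graph, demo_definition,
            {demo_definition.anchor_stimulus: -1.0}, 10, seed=1,
            cfg=fn.PropagationConfig(acceptance_fraction=0.0),
        )
        assert ens.n_solutions == 10
        assert ens.provenance["attempts"] == 10

    def test_same_seed_identical_ensembles(self, demo_graph, demo_definition):
        kw = dict(
            stimulus_set={demo_definition.anchor_stimulus: -1.0},
            n_solutions=5, seed=77,
            cfg=fn.PropagationConfig(acceptance_fraction=0.0),
        )
        a = fn.sample_solutions(demo_graph, demo_definition, **kw)
        b = fn.sample_solutions(demo_graph, demo_definition, **kw)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.weight_seeds == b.weight_seeds

    def test_accepted_solutions_meet_acceptance_fraction(
        self, demo_graph, demo_definition
    ):
        cfg = fn.PropagationConfig(acceptance_fraction=0.75, max_attempts=2000)
        ens = fn.sample_solutions(
            demo_graph, demo_definition,
            {demo_definition.anchor_stimulus: -1.0}, 20, seed=5, cfg=cfg,
        )
        fracs = np.array(ens.satisfied_fractions, dtype=float)
        assert fracs.mean() >= 0.75

    def test_impossible_constraint_raises_with_diagnostics(self):
        # A -(+)-> B clamped A=+1 forces activity(B) > 0, but the definition
        # demands B inhibited: nothing can ever be accepted.
        g = fn.InteractomeGraph()
        g.add_interaction(fn.Interaction(source="A", target="B", sign=+1, directed=True))
        defn = fn.DiseaseDefinition(
            effectors=[fn.Effector(protein="B", direction=-1, motives=frozenset({"M1"}))],
            anchor_stimulus="A",
        )
        cfg = fn.PropagationConfig(acceptance_fraction=1.0, max_attempts=20)
        with pytest.raises(SamplerFailureError) as err:
            fn.sample_solutions(g, defn, {"A": 1.0}, 5, seed=0, cfg=cfg)
        assert err.value.diagnostics["attempts"] == 20

    def test_shortfall_fills_with_best_rejects_and_warns(self):
        # B hears a direct activating path and an indirect inhibiting one, so
        # its sign depends on the weight draw: only some draws satisfy y_B=-1
        g = fn.InteractomeGraph()
        g.add_interaction(fn.Interaction(source="A", target="B", sign=+1, directed=True))
        g.add_interaction(fn.Interaction(source="A", target="C", sign=+1, directed=True))
        g.add_interaction(fn.Interaction(source="C", target="B", sign=-1, directed=True))
        defn = fn.DiseaseDefinition(
            effectors=[
                fn.Effector(protein="B", direction=-1, motives=frozenset({"M1"})),
            ],
            anchor_stimulus="A",
        )
        cfg = fn.PropagationConfig(acceptance_fraction=1.0, max_attempts=30)
        with pytest.warns(UserWarning, match="best rejects"):
            ens = fn.sample_solutions(g, defn, {"A": 1.0}, 10, seed=0, cfg=cfg)
        assert ens.n_solutions == 10
        assert any(f >= 1.0 for f in ens.satisfied_fractions)


class TestModulated:
    def test_all_zero_ensemble_is_empty(self):
        ens = fn.SolutionEnsemble(protein_index=["A", "B"], matrix=np.zeros((3, 2)))
        assert fn.modulated_proteins(ens) == set()

    def test_single_nonzero_activity(self):
        m = np.zeros((2, 3))
        m[0, 1] = 0.4
        ens = fn.SolutionEnsemble(protein_index=["A", "B", "C"], matrix=m)
        assert fn.modulated_proteins(ens) == {"B"}

    def test_epsilon_boundary(self):
        m = np.full((1, 1), MODULATION_EPSILON / 2)
        ens = fn.SolutionEnsemble(protein_index=["A"], matrix=m)
        assert fn.modulated_proteins(ens) == set()
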