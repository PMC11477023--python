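"""Sampling-based signal propagation over the signed interactome.

This is the virtual-patient engine: each solution draws a random signed
weight configuration for the network, clamps the stimulus nodes (the
α-Gal A-deficiency anchor plus any further inducing effectors), propagates
the signal iteratively through the breadth-limited neighbourhood of the
stimulus, and is accepted iff the resulting activity signs reproduce at
least `acceptance_fraction` of the disease definition's effector directions.
An ensemble of accepted solutions plays the role of a cohort of virtual
individuals: each assigns every protein a predicted activity in [-1, 1].

The update rule for a non-clamped node i is

    a_i ← transfer(damping · Σ_j w_ji a_j)

run synchronously to a fixed point (or 100 sweeps), where w_ji carries the
edge sign and `transfer` is tanh or a hard clip to [-1, 1]. Nodes outside
the stimulus neighbourhood keep activity exactly 0 and never count as
modulated.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

from .disease import DiseaseDefinition
from .ensemble import SolutionEnsemble
from .errors import SamplerFailureError, ValidationError
from .interactome import InteractomeGraph

MODULATION_EPSILON = 1e-6

MAX_SWEEPS = 100
CONVERGENCE_TOL = 1e-12


@dataclass
class PropagationConfig:
    max_depth: int = 3
    damping: float = 0.9
    transfer: str = "tanh"  # or "clip-linear"
    weight_prior: tuple[float, float] = (0.1, 1.0)
    acceptance_fraction: float = 0.75
    max_attempts: int | None = None  # default: 50 × n_solutions

    def __post_init__(self):
        if not 0 < self.damping <= 1:
            raise ValidationError(f"damping must be in (0,1], got {self.damping}")
        if not 0 <= self.acceptance_fraction <= 1:
            raise ValidationError("acceptance_fraction must be in [0,1]")
        if self.transfer not in ("tanh", "clip-linear"):
            raise ValidationError(f"unknown transfer {self.transfer!r}")
        lo, hi = self.weight_prior
        if not (0 < lo <= hi):
            raise ValidationError("weight_prior bounds must satisfy 0 < low <= high")


def _transfer(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(x)
    return np.clip(x, -1.0, 1.0)


def _arc_arrays(graph: InteractomeGraph, order: dict[str, int]):
    """Per-arc (row=target, col=source) indices plus the owning edge index.

    Undirected edges contribute two arcs sharing one weight draw.
    """
    rows, cols, edge_of_arc, signs = [], [], [], []
    for ei, e in enumerate(graph.interactions):
        s, t = order[e.source], order[e.target]
        rows.append(t)
        cols.append(s)
        edge_of_arc.append(ei)
        signs.append(e.sign)
        if not e.directed:
            rows.append(s)
            cols.append(t)
            edge_of_arc.append(ei)
            signs.append(e.sign)
    return (
        np.asarray(rows, dtype=np.intp),
        np.asarray(cols, dtype=np.intp),
        np.asarray(edge_of_arc, dtype=np.intp),
        np.asarray(signs, dtype=float),
    )


def _reachable_within(graph: InteractomeGraph, sources, max_depth: int) -> set[str]:
    dig = graph.as_digraph()
    reached: set[str] = set()
    for s in sources:
        reached.update(
            nx.single_source_shortest_path_length(dig, s, cutoff=max_depth)
        )
    return reached


def propagate(
    graph: InteractomeGraph,
    edge_weights,
    stimulus: dict[str, float],
    cfg: PropagationConfig | None = None,
) -> dict[str, float]:
    """Run one propagation sweep sequence; returns activity per protein.

    `edge_weights` maps each Interaction (or its list index) to a signed
    weight; undirected edges carry the same weight in both directions.
    """
    cfg = cfg or PropagationConfig()
    order = {p: i for i, p in enumerate(graph.protein_ids())}
    for s in stimulus:
        if s not in order:
            raise ValidationError(f"stimulus node {s!r} not in graph")

    weights = np.empty(len(graph.interactions))
    if isinstance(edge_weights, dict):
        for ei, e in enumerate(graph.interactions):
            weights[ei] = edge_weights.get(e, edge_weights.get(ei, 0.0))
    else:
        weights[:] = np.asarray(edge_weights, dtype=float)
    if not np.all(np.isfinite(weights)):
        raise ValidationError("edge weights must be finite")

    rows, cols, edge_of_arc, _ = _arc_arrays(graph, order)
    arc_w = weights[edge_of_arc]
    n = len(order)
    W = sparse.coo_matrix((arc_w, (rows, cols)), shape=(n, n)).tocsr()

    reachable = _reachable_within(graph, stimulus, cfg.max_depth)
    activities = _sweep(W, order, stimulus, reachable, cfg)
    names = list(order)
    return {names[i]: float(activities[i]) for i in range(n)}


def _sweep(W, order, stimulus, reachable, cfg) -> np.ndarray:
    n = len(order)
    a = np.zeros(n)
    clamp_idx = np.array([order[s] for s in stimulus], dtype=np.intp)
    clamp_val = np.array([stimulus[s] for s in stimulus], dtype=float)
    reach_mask = np.zeros(n, dtype=bool)
    reach_mask[[order[p] for p in reachable]] = True
    free_mask = reach_mask.copy()
    free_mask[clamp_idx] = False

    a[clamp_idx] = clamp_val
    for _ in range(MAX_SWEEPS):
        new = _transfer(cfg.damping * (W @ a), cfg.transfer)
        new[~free_mask] = 0.0
        new[clamp_idx] = clamp_val
        assert np.all(np.abs(new) <= 1.0 + 1e-12)
        if np.max(np.abs(new - a)) < CONVERGENCE_TOL:
            a = new
            break
        a = new
    return a


def sample_solutions(
    graph: InteractomeGraph,
    defn: DiseaseDefinition,
    stimulus_set: dict[str, float],
    n_solutions: int,
    seed: int,
    cfg: PropagationConfig | None = None,
) -> SolutionEnsemble:
    """Accept/reject sampling of weight configurations into an ensemble.

    Each attempt draws edge-weight magnitudes from the configured prior
    (multiplied by the edge sign), propagates from the clamped stimulus set,
    and keeps the solution iff sign(activity) matches the effector direction
    for at least `acceptance_fraction` of the effectors reachable within
    `max_depth`. If `max_attempts` is exhausted before `n_solutions`
    acceptances, the best rejected attempts fill the gap with a warning.
    """
    cfg = cfg or PropagationConfig()
    order = {p: i for i, p in enumerate(graph.protein_ids())}
    for s in stimulus_set:
        if s not in order:
            raise ValidationError(f"stimulus node {s!r} not in graph")
    n = len(order)
    names = list(order)

    rows, cols, edge_of_arc, _ = _arc_arrays(graph, order)
    edge_signs = np.array([e.sign for e in graph.interactions], dtype=float)
    reachable = _reachable_within(graph, stimulus_set, cfg.max_depth)
    eff_reachable = [
        e for e in defn.effectors if e.protein in reachable and e.protein in order
    ]
    eff_idx = np.array([order[e.protein] for e in eff_reachable], dtype=np.intp)
    eff_dir = np.array([e.direction for e in eff_reachable], dtype=float)

    max_attempts = cfg.max_attempts or 50 * n_solutions
    rng = np.random.default_rng(seed)
    lo, hi = cfg.weight_prior

    accepted: list[tuple[np.ndarray, int, float]] = []
    best: list[tuple[float, int, int, np.ndarray]] = []  # min-heap of rejects
    attempts = 0
    while len(accepted) < n_solutions and attempts < max_attempts:
        attempts += 1
        attempt_seed = int(rng.integers(2**31))
        wrng = np.random.default_rng(attempt_seed)
        mags = wrng.uniform(lo, hi, size=len(graph.interactions))
        weights = mags * edge_signs
        arc_w = weights[edge_of_arc]
        W = sparse.coo_matrix((arc_w, (rows, cols)), shape=(n, n)).tocsr()
        a = _sweep(W, order, stimulus_set, reachable, cfg)

        if len(eff_idx):
            act = a[eff_idx]
            matched = (np.abs(act) > MODULATION_EPSILON) & (np.sign(act) == eff_dir)
            frac = float(np.mean(matched))
        else:
            frac = 0.0
        if frac >= cfg.acceptance_fraction:
            accepted.append((a, attempt_seed, frac))
        else:
            heapq.heappush(best, (frac, -attempts, attempt_seed, a))
            if len(best) > n_solutions:
                heapq.heappop(best)

    if not accepted and cfg.acceptance_fraction > 0:
        fracs = [b[0] for b in best]
        raise SamplerFailureError(
            f"no solution accepted in {attempts} attempts "
            f"(acceptance_fraction={cfg.acceptance_fraction})",
            diagnostics={
                "attempts": attempts,
                "best_fraction": max(fracs) if fracs else None,
                "n_reachable_effectors": len(eff_reachable),
            },
        )
    if len(accepted) < n_solutions:
        shortfall = n_solutions - len(accepted)
        warnings.warn(
            f"only {len(accepted)}/{n_solutions} solutions accepted after "
            f"{attempts} attempts; filling with {shortfall} best rejects",
            stacklevel=2,
        )
        fill = sorted(best, key=lambda b: (-b[0], b[1]))[:shortfall]
        for frac, _, s, a in fill:
            accepted.append((a, s, frac))

    matrix = np.vstack([a for a, _, _ in accepted])
    return SolutionEnsemble(
        protein_index=names,
        matrix=matrix,
        weight_seeds=[s for _, s, _ in accepted],
        satisfied_fractions=[f for _, _, f in accepted],
        provenance={
            "seed": seed,
            "attempts": attempts,
            "stimulus": dict(stimulus_set),
            "config": {
                "max_depth": cfg.max_depth,
                "damping": cfg.damping,
                "transfer": cfg.transfer,
                "weight_prior": list(cfg.weight_prior),
                "acceptance_fraction": cfg.acceptance_fraction,
            },
        },
    )


def modulated_proteins(
    ensemble: SolutionEnsemble, epsilon: float = MODULATION_EPSILON
) -> set[str]:
    """Proteins with |activity| > epsilon in at least one solution."""
    if ensemble.n_solutions == 0:
        raise ValidationError("ensemble is empty")
    mask = np.any(np.abs(ensemble.matrix) > epsilon, axis=0)
    return {p for p, m in zip(ensemble.protein_index, mask) if m}
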