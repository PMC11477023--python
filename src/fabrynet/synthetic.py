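"""Synthetic study inputs: network, disease definition, annotations, planted screens.

The real inputs of the study — a curated human interactome, a
bibliography-derived Fabry-disease characterization, and protein-atlas
annotations — are proprietary or manually assembled. This module emulates
each of them at configurable scale so that every downstream stage is
testable end to end. The study-scale preset mirrors the printed study
dimensions: a 9226-protein / 83,011-relationship network, seven motives of
sizes 13, 16, 8, 10, 4, 17 and 27 sharing 92 unique effector proteins, and
a 1000-solution ensemble.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .disease import DiseaseDefinition, Effector
from .ensemble import SolutionEnsemble
from .errors import ConfigError
from .filters import AnnotationRecord, load_location_vocab
from .interactome import Interaction, InteractomeGraph, Protein

# Printed study dimensions used by the study-scale preset.
STUDY_N_PROTEINS = 9226
STUDY_N_EDGES = 83011
STUDY_MOTIVE_SIZES = (13, 16, 8, 10, 4, 17, 27)
STUDY_MOTIVE_NAMES = (
    "aGalA mutation and Gb3 accumulation",
    "oxidative stress",
    "impaired autophagy",
    "cellular death",
    "lipid raft disruption",
    "compromised energy metabolism",
    "inflammation and immune response",
)
STUDY_UNIQUE_EFFECTORS = 92
STUDY_N_SOLUTIONS = 1000


@dataclass
class SyntheticConfig:
    n_proteins: int = 200
    n_edges: int = 800
    network_model: str = "scale-free"  # or "erdos-renyi"
    motive_sizes: tuple[int, ...] = STUDY_MOTIVE_SIZES
    unique_effectors: int = STUDY_UNIQUE_EFFECTORS
    frac_positive_sign: float = 0.7
    frac_directed: float = 0.3
    frac_plasma: float = 0.3
    frac_urine: float = 0.15
    frac_neuronal: float = 0.25
    frac_vascular: float = 0.2
    frac_negative_direction: float = 0.0
    degree_bias: bool = True
    seed: int = 0

    def __post_init__(self):
        max_edges = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_edges > max_edges:
            raise ConfigError(
                f"{self.n_edges} edges infeasible for {self.n_proteins} proteins"
            )
        if self.unique_effectors > sum(self.motive_sizes):
            raise ConfigError("unique_effectors exceeds total motive memberships")
        if self.unique_effectors < len(self.motive_sizes):
            raise ConfigError("need at least one unique protein per motive")
        for name in ("frac_plasma", "frac_urine", "frac_neuronal", "frac_vascular",
                     "frac_positive_sign", "frac_directed", "frac_negative_direction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")


def study_scale_config(seed: int = 0) -> SyntheticConfig:
    """Preset matching every printed scale number of the study."""
    return SyntheticConfig(
        n_proteins=STUDY_N_PROTEINS,
        n_edges=STUDY_N_EDGES,
        network_model="scale-free",
        motive_sizes=STUDY_MOTIVE_SIZES,
        unique_effectors=STUDY_UNIQUE_EFFECTORS,
        seed=seed,
    )


def demo_small_config(seed: int = 0) -> SyntheticConfig:
    """Small preset for fast end-to-end runs (200 nodes)."""
    return SyntheticConfig(n_proteins=200, n_edges=800, seed=seed)


def _protein_id(i: int, width: int) -> str:
    return f"P{i:0{width}d}"


def generate_network(cfg: SyntheticConfig) -> InteractomeGraph:
    """Signed synthetic interactome with the exact requested edge count.

    Scale-free topology comes from preferential attachment, then random
    edges are added or removed to hit `n_edges` exactly; signs and
    directedness are drawn per edge at the configured fractions.
    """
    rng = np.random.default_rng(cfg.seed)
    n, e = cfg.n_proteins, cfg.n_edges
    nx_seed = int(rng.integers(2**31))
    if cfg.network_model == "erdos-renyi":
        g = nx.gnm_random_graph(n, e, seed=nx_seed)
    elif cfg.network_model == "scale-free":
        m = max(1, round(e / max(n - 1, 1)))
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
        g = _adjust_edge_count(g, e, rng)
    else:
        raise ConfigError(f"unknown network_model {cfg.network_model!r}")

    width = len(str(n - 1))
    graph = InteractomeGraph()
    for i in range(n):
        graph.add_protein(Protein(id=_protein_id(i, width), gene_symbol=f"G{i}"))
    edges = sorted(g.edges())
    signs = np.where(rng.random(len(edges)) < cfg.frac_positive_sign, 1, -1)
    directed = rng.random(len(edges)) < cfg.frac_directed
    for (u, v), s, d in zip(edges, signs, directed):
        graph.add_interaction(
            Interaction(
                source=_protein_id(u, width),
                target=_protein_id(v, width),
                sign=int(s),
                directed=bool(d),
                kind="regulatory" if d else "physical",
            )
        )
    return graph


def _adjust_edge_count(g: nx.Graph, target: int, rng: np.random.Generator) -> nx.Graph:
    nodes = list(g.nodes())
    while g.number_of_edges() < target:
        u, v = rng.choice(len(nodes), size=2, replace=False)
        if not g.has_edge(nodes[u], nodes[v]):
            g.add_edge(nodes[u], nodes[v])
    if g.number_of_edges() > target:
        excess = g.number_of_edges() - target
        edges = sorted(g.edges())
        # prefer removing edges between high-degree nodes to keep the giant
        # component intact
        scores = np.array([g.degree(u) + g.degree(v) for u, v in edges], dtype=float)
        order = np.argsort(-scores, kind="stable")
        removed = 0
        for i in order:
            if removed >= excess:
                break
            u, v = edges[i]
            if g.degree(u) > 1 and g.degree(v) > 1:
                g.remove_edge(u, v)
                removed += 1
    return g


def generate_disease_definition(
    graph: InteractomeGraph, cfg: SyntheticConfig
) -> DiseaseDefinition:
    """Sample effectors and assign motive memberships with controlled overlap.

    Exactly `cfg.unique_effectors` distinct proteins cover motives of the
    configured sizes; the Σsizes − unique surplus memberships are assigned
    as overlaps (one protein in two or more motives). High-degree nodes are
    preferred as effectors when `degree_bias` is set, mimicking the
    literature bias toward well-connected proteins.
    """
    if graph.n_proteins < cfg.unique_effectors:
        raise ConfigError("graph smaller than the requested number of effectors")
    rng = np.random.default_rng(cfg.seed + 1)
    ids = graph.protein_ids()
    if cfg.degree_bias:
        dig = graph.as_digraph()
        deg = np.array([dig.degree(p) for p in ids], dtype=float) + 1.0
        probs = deg / deg.sum()
    else:
        probs = None
    chosen = list(
        rng.choice(ids, size=cfg.unique_effectors, replace=False, p=probs)
    )

    motive_ids = [f"M{i+1}" for i in range(len(cfg.motive_sizes))]
    sizes = list(cfg.motive_sizes)
    total = sum(sizes)
    overlap = total - cfg.unique_effectors

    # base allocation: each motive gets b_m >= 1 distinct "home" proteins,
    # Σ b_m = unique; surplus memberships become overlaps.
    base = sizes[:]
    order = np.argsort(-np.asarray(sizes), kind="stable")
    remaining = overlap
    while remaining > 0:
        for m in order:
            if remaining == 0:
                break
            if base[m] > 1:
                base[m] -= 1
                remaining -= 1

    membership: dict[str, set[str]] = {p: set() for p in chosen}
    cursor = 0
    home: dict[str, list[str]] = {}
    for mid, b in zip(motive_ids, base):
        home[mid] = chosen[cursor : cursor + b]
        for p in home[mid]:
            membership[p].add(mid)
        cursor += b

    # fill each motive to its declared size with proteins homed elsewhere
    for mid, size in zip(motive_ids, sizes):
        deficit = size - len(home[mid])
        if deficit <= 0:
            continue
        pool = [p for p in chosen if mid not in membership[p]]
        picks = rng.choice(len(pool), size=deficit, replace=False)
        for i in picks:
            membership[pool[i]].add(mid)

    directions = np.where(
        rng.random(len(chosen)) < cfg.frac_negative_direction, -1, +1
    )
    effectors = [
        Effector(protein=p, direction=int(d), motives=frozenset(membership[p]))
        for p, d in zip(chosen, directions)
    ]
    # the anchor models the alpha-Gal A deficiency node: clamped -1 downstream
    anchor = home[motive_ids[0]][0]
    motive_table = {
        mid: (name, size)
        for mid, name, size in zip(
            motive_ids,
            (STUDY_MOTIVE_NAMES + tuple(f"motive {m}" for m in motive_ids))[
                : len(motive_ids)
            ],
            sizes,
        )
    }
    defn = DiseaseDefinition(
        effectors=effectors, motive_table=motive_table, anchor_stimulus=anchor
    )
    defn.validate_motive_sizes()
    return defn


def align_directions(
    graph: InteractomeGraph,
    defn: DiseaseDefinition,
    anchor_clamp: float = -1.0,
    cfg=None,
) -> DiseaseDefinition:
    """Set effector directions to the signs the disease mechanism produces.

    A bibliographic characterization records the direction each effector is
    *observed* to take in patients — i.e. the sign the disease signalling
    actually imposes. The synthetic analogue: propagate from the clamped
    anchor with mid-prior weights and read off each effector's activity
    sign. Effectors the signal does not reach keep their configured
    direction. Without this alignment a random direction assignment would
    contradict the network's own sign structure and no sampled solution
    could reproduce the definition.
    """
    from .propagation import MODULATION_EPSILON, PropagationConfig, propagate

    cfg = cfg or PropagationConfig()
    lo, hi = cfg.weight_prior
    mid = (lo + hi) / 2.0
    weights = [mid * e.sign for e in graph.interactions]
    acts = propagate(graph, weights, {defn.anchor_stimulus: anchor_clamp}, cfg)
    effectors = []
    for e in defn.effectors:
        a = acts.get(e.protein, 0.0)
        direction = int(np.sign(a)) if abs(a) > MODULATION_EPSILON else e.direction
        effectors.append(
            Effector(protein=e.protein, direction=direction, motives=e.motives)
        )
    return DiseaseDefinition(
        effectors=effectors,
        motive_table=dict(defn.motive_table),
        anchor_stimulus=defn.anchor_stimulus,
    )


_EVIDENCE_LEVELS = ("enhanced", "supported", "uncertain")
_EVIDENCE_PROBS = (0.5, 0.3, 0.2)


def generate_annotations(
    proteins: list[str], cfg: SyntheticConfig
) -> list[AnnotationRecord]:
    """Per-protein measurability flags and location terms at the configured rates.

    Neuronal terms are drawn from the curated subcellular vocabulary and
    vascular terms from the curated tissue vocabulary, so the configured
    fractions translate directly into location-code fractions regardless of
    the atlas evidence level drawn.
    """
    vocab = load_location_vocab()
    neuronal_terms = sorted(vocab["neuronal"]["subcellular_uniprot"])
    vascular_terms = sorted(vocab["vascular"]["tissue_uniprot"])
    rng = np.random.default_rng(cfg.seed + 2)
    records = []
    for p in proteins:
        subcellular: set[str] = set()
        tissue: set[str] = set()
        if rng.random() < cfg.frac_neuronal:
            subcellular.add(neuronal_terms[int(rng.integers(len(neuronal_terms)))])
        if rng.random() < cfg.frac_vascular:
            tissue.add(vascular_terms[int(rng.integers(len(vascular_terms)))])
        records.append(
            AnnotationRecord(
                protein=p,
                plasma=bool(rng.random() < cfg.frac_plasma),
                urine=bool(rng.random() < cfg.frac_urine),
                subcellular_terms=frozenset(subcellular),
                tissue_terms=frozenset(tissue),
                evidence=_EVIDENCE_LEVELS[
                    int(rng.choice(len(_EVIDENCE_LEVELS), p=_EVIDENCE_PROBS))
                ],
            )
        )
    return records


@dataclass
class PlantedScreen:
    """A solution matrix with k informative proteins separating two cohorts."""

    ensemble: SolutionEnsemble
    labels: np.ndarray  # 0 = low-damage cohort, 1 = high-damage cohort
    informative: list[str] = field(default_factory=list)


def plant_solution_matrix(
    n_solutions: int,
    n_proteins: int,
    k_informative: int,
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> PlantedScreen:
    """Planted-signal benchmark matrix for the classifier screen.

    Two balanced cohorts; the k informative proteins differ in mean activity
    by `effect_size` standardized units (i.e. effect_size × noise_sd raw
    units), all activities clipped to [-1, 1]; the remaining proteins are
    exchangeable between cohorts.
    """
    if k_informative > n_proteins:
        raise ConfigError("k_informative exceeds n_proteins")
    rng = np.random.default_rng(seed)
    n_low = n_solutions // 2
    labels = np.zeros(n_solutions, dtype=int)
    labels[n_low:] = 1
    width = len(str(n_proteins - 1))
    names = [_protein_id(i, width) for i in range(n_proteins)]
    informative = sorted(rng.choice(n_proteins, size=k_informative, replace=False))

    matrix = rng.normal(0.0, noise_sd, size=(n_solutions, n_proteins))
    shift = effect_size * noise_sd
    for j in informative:
        matrix[labels == 0, j] -= shift / 2
        matrix[labels == 1, j] += shift / 2
    matrix = np.clip(matrix, -1.0, 1.0)
    ensemble = SolutionEnsemble(
        protein_index=names,
        matrix=matrix,
        provenance={
            "generator": "plant_solution_matrix",
            "seed": seed,
            "k_informative": k_informative,
            "effect_size": effect_size,
            "noise_sd": noise_sd,
        },
    )
    return PlantedScreen(
        ensemble=ensemble, labels=labels, informative=[names[j] for j in informative]
    )
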