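"""Stimulus screen: which effectors can induce the disease definition.

Each candidate effector is clamped (alone, beside the anchor deficiency
node) and its ensemble is scored by how many of the remaining effectors at
hop distances 1–3 it stimulates with the characterization sign, weighting
closer effectors more. Candidates reaching at least 75% of the maximum
achievable weighted coverage join the anchor in the stimulus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .disease import DiseaseDefinition
from .ensemble import SolutionEnsemble
from .errors import ValidationError
from .interactome import InteractomeGraph, distances_from
from .propagation import MODULATION_EPSILON

DEFAULT_DISTANCE_WEIGHTS = {1: 3.0, 2: 2.0, 3: 1.0}


@dataclass
class InductionScore:
    effector: str
    score: float  # percent of the maximum achievable weighted coverage
    per_distance_hits: dict[int, float] = field(default_factory=dict)
    normalizer_zero: bool = False


def induction_score(
    graph: InteractomeGraph,
    ensemble: SolutionEnsemble,
    candidate: str,
    defn: DiseaseDefinition,
    distance_weights: dict[int, float] | None = None,
    epsilon: float = MODULATION_EPSILON,
) -> InductionScore:
    """Distance-weighted sign-correct coverage of the other effectors.

    Per solution, every effector at hop distance d ∈ {1,2,3} from the
    candidate whose activity sign matches its characterization direction
    contributes distance_weights[d]; the solution scores are averaged over
    the ensemble and normalized by the score a solution would attain if
    every reachable effector matched (globally, over all distances).
    Effectors beyond 3 hops are excluded from numerator and normalizer.
    A candidate with no reachable effector scores 0 with a flag.
    """
    weights = distance_weights or DEFAULT_DISTANCE_WEIGHTS
    directions = defn.directions()
    if candidate not in directions:
        raise ValidationError(f"candidate {candidate!r} is not an effector")
    max_depth = max(weights)
    dist = distances_from(graph, candidate, max_depth)

    targets = [
        (p, d)
        for p, d in dist.items()
        if p != candidate and p in directions and ensemble.has_protein(p) and d in weights
    ]
    max_score = sum(weights[d] for _, d in targets)
    if max_score == 0:
        return InductionScore(
            effector=candidate,
            score=0.0,
            per_distance_hits={d: 0.0 for d in weights},
            normalizer_zero=True,
        )

    V = ensemble.columns([p for p, _ in targets])  # n_solutions × n_targets
    y = np.array([directions[p] for p, _ in targets], dtype=float)
    w = np.array([weights[d] for _, d in targets], dtype=float)
    matched = (np.abs(V) > epsilon) & (np.sign(V) == y)
    per_solution = matched @ w
    mean_score = float(per_solution.mean())

    hits = {}
    for d in sorted(weights):
        cols = [i for i, (_, dd) in enumerate(targets) if dd == d]
        hits[d] = float(matched[:, cols].sum(axis=1).mean()) if cols else 0.0
    return InductionScore(
        effector=candidate,
        score=100.0 * mean_score / max_score,
        per_distance_hits=hits,
    )


def select_stimuli(
    scores: list[InductionScore],
    threshold: float = 75.0,
    anchor: str | None = None,
) -> list[str]:
    """Anchor plus every effector scoring at least the threshold.

    Ordered deterministically: anchor first, then descending score, then id.
    """
    if anchor is None:
        raise ValidationError("an anchor stimulus must be provided")
    selected = sorted(
        (s for s in scores if s.score >= threshold and s.effector != anchor),
        key=lambda s: (-s.score, s.effector),
    )
    return [anchor] + [s.effector for s in selected]
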