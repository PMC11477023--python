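"""Screen every effector for its capacity to induce the disease definition.

Each candidate is clamped beside the anchor, a small ensemble is sampled,
and its distance-weighted sign-correct coverage of the remaining effectors
is scored; candidates reaching >= 75% of the maximum join the stimulus set.
"""

import json
from pathlib import Path

import pandas as pd

import fabrynet as fn

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SOLUTIONS_PER_CANDIDATE = 20


def main():
    graph = fn.read_network(OUT / "network.tsv")
    defn = fn.read_disease_definition(OUT / "disease_definition.csv")
    anchor = defn.anchor_stimulus

    scores = []
    for i, eff in enumerate(defn.effectors):
        if eff.protein == anchor:
            continue
        ens = fn.sample_solutions(
            graph,
            defn,
            {anchor: -1.0, eff.protein: float(eff.direction)},
            SOLUTIONS_PER_CANDIDATE,
            seed=SEED * 100003 + i,
            cfg=fn.PropagationConfig(acceptance_fraction=0.0),
        )
        scores.append(fn.induction_score(graph, ens, eff.protein, defn))

    selected = fn.select_stimuli(scores, threshold=75.0, anchor=anchor)
    pd.DataFrame(
        {
            "effector": [s.effector for s in scores],
            "score": [s.score for s in scores],
            "hits_d1": [s.per_distance_hits.get(1, 0.0) for s in scores],
            "hits_d2": [s.per_distance_hits.get(2, 0.0) for s in scores],
            "hits_d3": [s.per_distance_hits.get(3, 0.0) for s in scores],
        }
    ).sort_values("score", ascending=False).to_csv(
        OUT / "stimulus_scores.csv", index=False
    )
    with open(OUT / "stimulus_set.json", "w") as fh:
        json.dump(selected, fh)

    ranked = sorted(scores, key=lambda s: -s.score)
    print(f"scored {len(scores)} candidate effectors")
    print("top 5:", [(s.effector, round(s.score, 1)) for s in ranked[:5]])
    print(f"stimulus set ({len(selected)} members incl. anchor): {selected}")


if __name__ == "__main__":
    main()
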