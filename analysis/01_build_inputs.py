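"""Build the synthetic study inputs: signed interactome, disease definition,
protein annotations.

Emulates the study's proprietary inputs at demo scale (200 proteins) so the
whole analysis can run in seconds; the study-scale preset (9226 proteins,
83,011 relationships, 92 effectors) is available via
``fabrynet.study_scale_config``.
"""

from pathlib import Path

import fabrynet as fn
from fabrynet.filters import write_annotations
from fabrynet.synthetic import align_directions

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = fn.demo_small_config(seed=SEED)
    graph = fn.generate_network(cfg)
    defn = fn.generate_disease_definition(graph, cfg)
    defn = align_directions(graph, defn)
    annotations = fn.generate_annotations(graph.protein_ids(), cfg)

    fn.write_network(graph, OUT / "network.tsv")
    fn.write_disease_definition(defn, OUT / "disease_definition.csv")
    write_annotations(annotations, OUT / "annotations.csv")

    n_plasma = sum(a.plasma for a in annotations)
    n_urine = sum(a.urine for a in annotations)
    print(f"network: {graph.n_proteins} proteins, {graph.n_interactions} interactions")
    print(f"disease definition: {fn.unique_effectors(defn)} unique effectors "
          f"across {len(defn.motive_table)} motives; anchor {defn.anchor_stimulus}")
    print(f"annotations: {n_plasma} plasma-measurable, {n_urine} urine-measurable")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
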