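"""Sample the virtual-patient ensemble.

Clamps the anchor deficiency node to -1 (loss of function) and draws signed
weight configurations until 100 solutions reproduce at least 75% of the
effector directions, mirroring the construction of a 1000-solution disease
model at one-tenth scale.
"""

from pathlib import Path

import numpy as np

import fabrynet as fn
from fabrynet.filters import read_annotations  # noqa: F401  (input check)

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
N_SOLUTIONS = 100


def main():
    graph = fn.read_network(OUT / "network.tsv")
    defn = fn.read_disease_definition(OUT / "disease_definition.csv")

    cfg = fn.PropagationConfig(acceptance_fraction=0.75)
    ensemble = fn.sample_solutions(
        graph, defn, {defn.anchor_stimulus: -1.0}, N_SOLUTIONS, seed=SEED, cfg=cfg
    )
    ensemble.save(OUT / "ensemble.tsv", OUT / "ensemble_manifest.json")

    fracs = np.array(ensemble.satisfied_fractions, dtype=float)
    modulated = fn.modulated_proteins(ensemble)
    print(f"sampled {ensemble.n_solutions} solutions "
          f"({ensemble.provenance['attempts']} attempts)")
    print(f"mean satisfied fraction: {fracs.mean():.3f} (min {fracs.min():.3f})")
    print(f"modulated proteins: {len(modulated)} of {ensemble.n_proteins}")


if __name__ == "__main__":
    main()
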