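"""Screen every protein and feature-selected protein pair as a damage
classifier under threshold-averaging 10-fold cross-validation."""

from pathlib import Path

import numpy as np
import pandas as pd

import fabrynet as fn

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    ensemble = fn.SolutionEnsemble.load(OUT / "ensemble.tsv")
    defn = fn.read_disease_definition(OUT / "disease_definition.csv")
    table = pd.read_csv(OUT / "damage_table.csv")

    low = table.index[table["cohort"] == "low"].tolist()
    high = table.index[table["cohort"] == "high"].tolist()
    cohort = ensemble.subset(low + high)
    labels = np.array([0] * len(low) + [1] * len(high))

    cfg = fn.ScreenConfig(
        methods=("mrmr", "relieff", "wilcoxon-corr"),
        top_k=5,
        families=("glm-binomial", "naive-bayes"),
        seed=SEED,
    )
    out = fn.screen_all(cohort, labels, cfg)
    out.to_frame().to_csv(OUT / "screen_results.csv", index=False)

    print(f"cleaned variables: {len(out.kept_variables)} "
          f"(ordered pair universe {out.pair_universe}; "
          f"{out.n_pairs_evaluated} pairs evaluated)")
    print("top 5 classifiers:")
    for r in out.results[:5]:
        print(f"  {'+'.join(r.spec.variables):<12} {r.spec.family:<20} "
              f"acc {r.cv_accuracy:5.1f}%  p {r.cv_pvalue:.2e}")


if __name__ == "__main__":
    main()
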