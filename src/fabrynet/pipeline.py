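"""End-to-end orchestration: inputs → ensemble → cohorts → screen → filters.

Runs the whole study sequence under one seeded configuration and persists
every stage artifact (with checksums) into a run directory, so a rerun with
the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import damage, filters, propagation, screen, stimulus, synthetic
from .disease import write_disease_definition
from .errors import FabrynetError
from .interactome import write_network

STAGES = ("inputs", "stimuli", "ensemble", "stratify", "screen", "filter", "report")


@dataclass
class RunConfig:
    preset: str = "demo-small"  # demo-small | study-scale | custom
    network_path: str | None = None
    definition_path: str | None = None
    annotations_path: str | None = None
    n_solutions: int = 100
    q: float = 0.10
    k_folds: int = 10
    acceptance_fraction: float = 0.75
    sign_convention: str = "agreement"
    stimulus_screen: bool = False
    stimulus_threshold: float = 75.0
    stimulus_solutions: int = 20
    fs_methods: tuple[str, ...] = ("mrmr", "wilcoxon-corr")
    fs_top_k: int = 5
    pair_families: tuple[str, ...] = ("glm-binomial", "naive-bayes")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fs_methods", "pair_families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(FabrynetError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage in order; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": [], "artifacts": {}}

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    def finish_stage(name: str):
        manifest["stages"].append(name)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    stage = "inputs"
    try:
        graph, defn, get_annotations = _load_inputs(config)
        write_network(graph, out / "network.tsv")
        write_disease_definition(defn, out / "disease_definition.csv")
        record("network.tsv", out / "network.tsv")
        record("disease_definition.csv", out / "disease_definition.csv")
        finish_stage(stage)

        anchor = defn.anchor_stimulus
        clamp = {anchor: -1.0}
        pcfg = propagation.PropagationConfig(
            acceptance_fraction=config.acceptance_fraction
        )

        stage = "stimuli"
        if config.stimulus_screen:
            scores = []
            directions = defn.directions()
            for i, e in enumerate(defn.effectors):
                if e.protein == anchor:
                    continue
                ens = propagation.sample_solutions(
                    graph,
                    defn,
                    {anchor: -1.0, e.protein: float(e.direction)},
                    config.stimulus_solutions,
                    seed=config.seed * 100003 + i,
                    cfg=propagation.PropagationConfig(acceptance_fraction=0.0),
                )
                scores.append(stimulus.induction_score(graph, ens, e.protein, defn))
            selected = stimulus.select_stimuli(
                scores, threshold=config.stimulus_threshold, anchor=anchor
            )
            pd.DataFrame(
                {
                    "effector": [s.effector for s in scores],
                    "score": [s.score for s in scores],
                    "hits_d1": [s.per_distance_hits.get(1, 0.0) for s in scores],
                    "hits_d2": [s.per_distance_hits.get(2, 0.0) for s in scores],
                    "hits_d3": [s.per_distance_hits.get(3, 0.0) for s in scores],
                }
            ).to_csv(out / "stimulus_scores.csv", index=False)
            with open(out / "stimulus_set.json", "w") as fh:
                json.dump(selected, fh)
            record("stimulus_scores.csv", out / "stimulus_scores.csv")
            record("stimulus_set.json", out / "stimulus_set.json")
            clamp = {anchor: -1.0}
            for p in selected:
                if p != anchor:
                    clamp[p] = float(directions[p])
            finish_stage(stage)

        stage = "ensemble"
        ensemble = propagation.sample_solutions(
            graph, defn, clamp, config.n_solutions, seed=config.seed, cfg=pcfg
        )
        ensemble.save(out / "ensemble.tsv", out / "ensemble_manifest.json")
        record("ensemble.tsv", out / "ensemble.tsv")
        finish_stage(stage)

        stage = "stratify"
        dmg = damage.damage_table(
            ensemble, defn, q=config.q, sign_convention=config.sign_convention
        )
        dmg.to_csv(out / "damage_table.csv", index=False)
        record("damage_table.csv", out / "damage_table.csv")
        finish_stage(stage)

        stage = "screen"
        low = dmg.index[dmg["cohort"] == "low"].tolist()
        high = dmg.index[dmg["cohort"] == "high"].tolist()
        cohort = ensemble.subset(low + high)
        labels = np.array([0] * len(low) + [1] * len(high))
        scfg = screen.ScreenConfig(
            k_folds=config.k_folds,
            methods=config.fs_methods,
            top_k=config.fs_top_k,
            families=config.pair_families,
            seed=config.seed,
        )
        output = screen.screen_all(cohort, labels, scfg)
        output.to_frame().to_csv(out / "screen_results.csv", index=False)
        record("screen_results.csv", out / "screen_results.csv")
        manifest["screen"] = {
            "n_variables": len(output.kept_variables),
            "pair_universe": output.pair_universe,
            "n_pairs_evaluated": output.n_pairs_evaluated,
        }
        finish_stage(stage)

        stage = "filter"
        annotations = get_annotations()
        filters.write_annotations(list(annotations.values()), out / "annotations.csv")
        record("annotations.csv", out / "annotations.csv")
        known = filters.load_known_biomarkers()
        reference, threshold = filters.reference_threshold(known)
        stages = filters.filter_candidates(output.results, annotations, threshold)
        flagship = filters.prioritize(stages.stage3)
        for name, df in (
            ("stage1_above_threshold.csv", stages.stage1),
            ("stage2_measurable.csv", stages.stage2),
            ("stage3_located.csv", stages.stage3),
            ("flagship.csv", flagship),
        ):
            frame = df.copy()
            frame["variables"] = frame["variables"].map(";".join)
            frame.to_csv(out / name, index=False)
            record(name, out / name)
        manifest["filter"] = {
            "reference_biomarker": reference.gene_symbol,
            "threshold": threshold,
            "counts": stages.counts,
            "n_flagship": len(flagship),
        }
        finish_stage(stage)

        stage = "report"
        make_report(out)
        record("report.md", out / "report.md")
        finish_stage(stage)
    except FabrynetError as exc:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise StageError(stage, exc) from exc
    except Exception as exc:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise StageError(stage, exc) from exc
    return out


def _load_inputs(config: RunConfig):
    """Returns (graph, definition, annotation thunk).

    Annotations are loaded lazily because they are first needed at the
    filter stage; a missing annotation file therefore aborts there, with
    every earlier artifact already persisted.
    """
    if config.preset == "custom":
        from .disease import read_disease_definition
        from .interactome import read_network

        if not (config.network_path and config.definition_path):
            raise FabrynetError("custom preset needs network and definition paths")
        graph = read_network(config.network_path)
        defn = read_disease_definition(config.definition_path)

        def get_annotations():
            if not config.annotations_path:
                raise FabrynetError("custom preset needs an annotations path")
            return filters.read_annotations(config.annotations_path)

        return graph, defn, get_annotations

    if config.preset == "demo-small":
        cfg = synthetic.demo_small_config(seed=config.seed)
    elif config.preset == "study-scale":
        cfg = synthetic.study_scale_config(seed=config.seed)
    else:
        raise FabrynetError(f"unknown preset {config.preset!r}")
    graph = synthetic.generate_network(cfg)
    defn = synthetic.generate_disease_definition(graph, cfg)
    defn = synthetic.align_directions(graph, defn)

    def get_annotations():
        records = synthetic.generate_annotations(graph.protein_ids(), cfg)
        return {r.protein: r for r in records}

    return graph, defn, get_annotations


def _md_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in df.iterrows():
        cells = [
            f"{v:.4g}" if isinstance(v, float) else str(v) for v in row.tolist()
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def make_report(run_dir) -> Path:
    """Markdown summary of whatever stages have completed in `run_dir`."""
    run_dir = Path(run_dir)
    lines = ["# Run report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"Completed stages: {', '.join(manifest.get('stages', []))}")
        lines.append("")

    scores_path = run_dir / "stimulus_scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path).sort_values("score", ascending=False)
        lines += ["## Stimulus screen (top 10)", "",
                  _md_table(scores.head(10)), ""]

    dmg_path = run_dir / "damage_table.csv"
    if dmg_path.exists():
        dmg = pd.read_csv(dmg_path)
        n_low = int((dmg["cohort"] == "low").sum())
        n_high = int((dmg["cohort"] == "high").sum())
        lines += [
            "## Damage stratification",
            "",
            f"- solutions: {len(dmg)}",
            f"- low-damage cohort: {n_low}",
            f"- high-damage cohort: {n_high}",
            "",
        ]

    screen_path = run_dir / "screen_results.csv"
    if screen_path.exists():
        res = pd.read_csv(screen_path)
        lines += ["## Top 20 classifiers", "",
                  _md_table(res.head(20).drop(columns=["final_params_json"])), ""]

    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    if "filter" in manifest:
        f = manifest["filter"]
        lines += [
            "## Candidate cascade",
            "",
            f"- reference biomarker: {f['reference_biomarker']} "
            f"(threshold {f['threshold']}%)",
            f"- above threshold: {f['counts']['above_threshold']}",
            f"- measurable in plasma/urine: {f['counts']['measurable']}",
            f"- neuronal/vascular location: {f['counts']['located']}",
            f"- flagship (≥90% accuracy, NV): {f['n_flagship']}",
            "",
        ]
    flagship_path = run_dir / "flagship.csv"
    if flagship_path.exists():
        fl = pd.read_csv(flagship_path)
        if len(fl):
            lines += ["## Flagship candidates", "", _md_table(fl), ""]
        else:
            lines += ["## Flagship candidates", "", "none", ""]

    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report


def fixture_report(outdir) -> Path:
    """Fixture-only mode: run the cascade on the packaged published tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    known = filters.load_known_biomarkers()
    reference, _ = filters.reference_threshold(known)
    results, annotations, locations = filters.candidate_fixture_inputs()
    stages = filters.filter_candidates(
        results, annotations, filters.PUBLISHED_REFERENCE_THRESHOLD, locations=locations
    )
    flagship = filters.prioritize(stages.stage3)
    lines = [
        "# Fixture cascade report",
        "",
        f"- reference biomarker: {reference.gene_symbol}",
        f"- threshold: {filters.PUBLISHED_REFERENCE_THRESHOLD}%",
        f"- candidates above threshold and measurable with location: "
        f"{len(stages.stage3)}",
        f"- flagship candidates: "
        f"{', '.join(v[0] for v in flagship['variables'])}",
        "",
    ]
    path = out / "fixture_report.md"
    path.write_text("\n".join(lines))
    return path
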