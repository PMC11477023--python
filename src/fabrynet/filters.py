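"""Candidate-selection cascade: reference threshold, measurability, location.

The screen produces hundreds of candidate classifiers; this module applies
the biological/clinical filters that turn them into actionable biomarker
candidates:

1. keep candidates with cross-validated accuracy strictly above the
   reference threshold set by the best *easily measurable* previously
   proposed biomarker (β-2-microglobulin in the original study);
2. keep candidates whose proteins are measurable in plasma and/or urine;
3. keep candidates located in neuronal and/or vascular compartments,
   matched against a closed term vocabulary (atlas-sourced tissue terms
   count only for "enhanced"/"supported" evidence entries);
4. prioritize flagships: accuracy ≥ 90% and both neuronal and vascular
   location (code NV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .disease import KnownBiomarker
from .errors import SelectionError, ValidationError

#: Accuracy threshold printed by the original study for its B2M reference.
#: Shipped as a constant because it cannot be re-derived from the rounded
#: table value (71).
PUBLISHED_REFERENCE_THRESHOLD = 70.5

LOCATION_CODES = ("N", "V", "NV", "none")
_MEASURABLE_EVIDENCE = frozenset({"enhanced", "supported"})


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-protein body-fluid measurability and location annotation."""

    protein: str
    plasma: bool = False
    urine: bool = False
    subcellular_terms: frozenset[str] = frozenset()
    tissue_terms: frozenset[str] = frozenset()
    evidence: str = "uncertain"  # enhanced / supported / uncertain / approved

    def __post_init__(self):
        object.__setattr__(
            self,
            "subcellular_terms",
            frozenset(t.strip().lower() for t in self.subcellular_terms),
        )
        object.__setattr__(
            self,
            "tissue_terms",
            frozenset(t.strip().lower() for t in self.tissue_terms),
        )


def _data_path(name: str):
    return resources.files("fabrynet.data").joinpath(name)


def load_location_vocab() -> dict:
    """Curated neuronal/vascular subcellular and tissue term vocabulary."""
    with _data_path("location_vocab.json").open() as fh:
        vocab = json.load(fh)
    for side in vocab.values():
        for key in side:
            side[key] = [t.lower() for t in side[key]]
    return vocab


def load_known_biomarkers() -> list[KnownBiomarker]:
    """Packaged transcription of the previously proposed biomarker table."""
    from .disease import read_known_biomarkers

    with resources.as_file(_data_path("known_biomarkers.csv")) as p:
        return read_known_biomarkers(p)


def load_candidate_fixture() -> pd.DataFrame:
    """Packaged 36-row transcription of the published candidate table."""
    with resources.as_file(_data_path("candidate_biomarkers.csv")) as p:
        return pd.read_csv(p)


def reference_threshold(
    known: list[KnownBiomarker], rule: str = "first-measurable"
) -> tuple[KnownBiomarker, float]:
    """Pick the reference biomarker and its accuracy as the screen threshold.

    `first-measurable`: rank by cv_accuracy descending and return the first
    plasma-measurable entry.
    """
    if rule != "first-measurable":
        raise ValidationError(f"unknown rule {rule!r}")
    ranked = sorted(
        (b for b in known if b.cv_accuracy is not None),
        key=lambda b: (-b.cv_accuracy, b.gene_symbol),
    )
    for b in ranked:
        if b.plasma_measurable:
            return b, float(b.cv_accuracy)
    raise SelectionError("no plasma-measurable biomarker among the candidates")


def classify_location(ann: AnnotationRecord, vocab: dict | None = None) -> str:
    """Assign N / V / NV / none from the annotation's terms.

    Subcellular terms match against the curated subcellular vocabularies;
    tissue terms against the tissue vocabularies. Atlas-sourced (THPA)
    tissue terms count only when the record's evidence level is "enhanced"
    or "supported"; curated (UniProt) terms always count.
    """
    vocab = vocab or load_location_vocab()
    atlas_ok = ann.evidence in _MEASURABLE_EVIDENCE

    def matches(side: dict) -> bool:
        if ann.subcellular_terms & set(side.get("subcellular_uniprot", [])):
            return True
        if atlas_ok and ann.subcellular_terms & set(side.get("subcellular_thpa", [])):
            return True
        if ann.tissue_terms & set(side.get("tissue_uniprot", [])):
            return True
        if atlas_ok and ann.tissue_terms & set(side.get("tissue_thpa", [])):
            return True
        return False

    neuronal = matches(vocab["neuronal"])
    vascular = matches(vocab["vascular"])
    if neuronal and vascular:
        return "NV"
    if neuronal:
        return "N"
    if vascular:
        return "V"
    return "none"


@dataclass
class FilterStages:
    """Nested candidate lists after each cascade stage."""

    stage1: pd.DataFrame  # accuracy above reference threshold
    stage2: pd.DataFrame  # + measurable in plasma and/or urine
    stage3: pd.DataFrame  # + neuronal and/or vascular location

    @property
    def counts(self) -> dict[str, int]:
        return {
            "above_threshold": len(self.stage1),
            "measurable": len(self.stage2),
            "located": len(self.stage3),
        }


def _results_frame(results) -> pd.DataFrame:
    """Normalize screen results to a frame with `variables` and `cv_accuracy`."""
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if "variables" not in df.columns:
            for alt in ("gene_symbol", "protein", "candidate"):
                if alt in df.columns:
                    df["variables"] = df[alt].map(lambda v: (v,))
                    break
    else:  # iterable of ScreenResult-like objects
        df = pd.DataFrame(
            {
                "variables": [tuple(r.spec.variables) for r in results],
                "cv_accuracy": [r.cv_accuracy for r in results],
            }
        )
    if "variables" not in df.columns or "cv_accuracy" not in df.columns:
        raise ValidationError("results need `variables` and `cv_accuracy`")
    df["variables"] = df["variables"].map(
        lambda v: (v,) if isinstance(v, str) else tuple(v)
    )
    return df


def filter_candidates(
    results,
    annotations: dict[str, AnnotationRecord] | None,
    threshold: float,
    vocab: dict | None = None,
    locations: dict[str, str] | None = None,
) -> FilterStages:
    """Run the three-stage cascade over screen results.

    Stage 1 keeps candidates with cv_accuracy strictly greater than the
    threshold; stage 2 keeps those whose every variable protein is plasma-
    and/or urine-measurable; stage 3 keeps those whose every variable has a
    location code other than "none". Precomputed `locations` override
    classification from `annotations`.
    """
    if not 0 <= threshold <= 100:
        raise ValidationError("threshold must be in [0,100]")
    df = _results_frame(results)
    vocab = vocab or load_location_vocab()
    annotations = annotations or {}

    def measurable(p: str) -> bool:
        ann = annotations.get(p)
        return bool(ann and (ann.plasma or ann.urine))

    def location(p: str) -> str:
        if locations is not None and p in locations:
            return locations[p]
        ann = annotations.get(p)
        return classify_location(ann, vocab) if ann else "none"

    stage1 = df[df["cv_accuracy"] > threshold].copy()
    stage2 = stage1[
        stage1["variables"].map(lambda vs: all(measurable(p) for p in vs)).astype(bool)
    ].copy()
    stage3 = stage2[
        stage2["variables"]
        .map(lambda vs: all(location(p) != "none" for p in vs))
        .astype(bool)
    ].copy()
    stage3["location"] = stage3["variables"].map(
        lambda vs: _combine_codes([location(p) for p in vs])
    )
    return FilterStages(stage1=stage1, stage2=stage2, stage3=stage3)


def _combine_codes(codes: list[str]) -> str:
    """Location of a multi-protein classifier: the codes all members share."""
    neuronal = all(c in ("N", "NV") for c in codes)
    vascular = all(c in ("V", "NV") for c in codes)
    if neuronal and vascular:
        return "NV"
    if neuronal:
        return "N"
    if vascular:
        return "V"
    return "none"


def prioritize(
    stage3: pd.DataFrame,
    acc_min: float = 90.0,
    required_location: str = "NV",
) -> pd.DataFrame:
    """Flagship selection: accuracy ≥ acc_min (inclusive) at the required code."""
    if required_location not in LOCATION_CODES:
        raise ValidationError(f"unknown location code {required_location!r}")
    df = stage3.copy()
    if "location" not in df.columns:
        raise ValidationError("stage-3 frame must carry a `location` column")
    out = df[(df["cv_accuracy"] >= acc_min) & (df["location"] == required_location)]
    key = out["variables"] if "variables" in out.columns else out.index
    return out.assign(_k=key.map(str)).sort_values(
        by=["cv_accuracy", "_k"], ascending=[False, True]
    ).drop(columns="_k")


def write_annotations(records: list[AnnotationRecord], path) -> None:
    rows = [
        {
            "protein": r.protein,
            "plasma": r.plasma,
            "urine": r.urine,
            "subcellular_terms": ";".join(sorted(r.subcellular_terms)),
            "tissue_terms": ";".join(sorted(r.tissue_terms)),
            "evidence": r.evidence,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path) -> dict[str, AnnotationRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        out[row.protein] = AnnotationRecord(
            protein=row.protein,
            plasma=str(row.plasma).lower() in ("true", "1"),
            urine=str(row.urine).lower() in ("true", "1"),
            subcellular_terms=frozenset(
                t for t in str(row.subcellular_terms).split(";") if t
            ),
            tissue_terms=frozenset(t for t in str(row.tissue_terms).split(";") if t),
            evidence=row.evidence,
        )
    return out


def candidate_fixture_inputs() -> tuple[pd.DataFrame, dict[str, AnnotationRecord], dict[str, str]]:
    """The packaged candidate table reshaped for `filter_candidates`.

    Returns (results frame, annotation records, printed location codes).
    """
    table = load_candidate_fixture()
    results = pd.DataFrame(
        {
            "variables": [(g,) for g in table["gene_symbol"]],
            "cv_accuracy": table["cv_accuracy"].astype(float),
        }
    )
    annotations = {
        row.gene_symbol: AnnotationRecord(
            protein=row.gene_symbol,
            plasma=bool(row.plasma),
            urine=bool(row.urine),
            evidence="supported",
        )
        for row in table.itertuples(index=False)
    }
    locations = dict(zip(table["gene_symbol"], table["location"]))
    return results, annotations, locations
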