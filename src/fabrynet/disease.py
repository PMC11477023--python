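"""Disease definition: effectors with direction and motive membership.

An *effector* is a protein functionally involved in the disease, carrying a
direction y ∈ {+1, −1} assigned during the bibliographic molecular
characterization (+1 pathologically activated, −1 inhibited/lost). Effectors
are grouped into *motives* — cellular-level pathological processes such as
oxidative stress or impaired autophagy — and one protein may belong to
several motives. The α-galactosidase A deficiency node is the anchor
stimulus: it is clamped to −1 (loss of function) in every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class Effector:
    protein: str
    direction: int = +1
    motives: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise ValidationError(
                f"effector direction must be +1 or -1, got {self.direction}"
            )
        if not self.motives:
            raise ValidationError(f"effector {self.protein} belongs to no motive")


@dataclass
class DiseaseDefinition:
    effectors: list[Effector] = field(default_factory=list)
    motive_table: dict[str, tuple[str, int]] = field(default_factory=dict)
    anchor_stimulus: str | None = None

    def __post_init__(self):
        seen = set()
        for e in self.effectors:
            if e.protein in seen:
                raise ValidationError(f"duplicate effector protein {e.protein}")
            seen.add(e.protein)

    def direction_of(self, protein: str) -> int:
        for e in self.effectors:
            if e.protein == protein:
                return e.direction
        raise KeyError(protein)

    def effector_ids(self) -> list[str]:
        return [e.protein for e in self.effectors]

    def directions(self) -> dict[str, int]:
        return {e.protein: e.direction for e in self.effectors}

    def motive_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for e in self.effectors:
            for m in sorted(e.motives):
                members.setdefault(m, []).append(e.protein)
        return members

    def validate_motive_sizes(self) -> None:
        """Check declared motive sizes against actual membership counts."""
        members = self.motive_members()
        for mid, (_, size) in self.motive_table.items():
            actual = len(members.get(mid, []))
            if actual != size:
                raise ValidationError(
                    f"motive {mid}: declared size {size}, actual membership {actual}"
                )


@dataclass(frozen=True)
class KnownBiomarker:
    """A previously proposed biomarker with its screen performance."""

    gene_symbol: str
    uniprot: str = ""
    cv_accuracy: float | None = None
    plasma_measurable: bool = False

    def __post_init__(self):
        if self.cv_accuracy is not None and not (0 <= self.cv_accuracy <= 100):
            raise ValidationError(
                f"cv_accuracy must be in [0,100], got {self.cv_accuracy}"
            )


def unique_effectors(defn: DiseaseDefinition) -> int:
    """Number of distinct effector proteins (motive overlap deduplicated)."""
    return len({e.protein for e in defn.effectors})


def read_disease_definition(path) -> DiseaseDefinition:
    """Read a `protein,direction,motives` CSV (motives semicolon-separated)."""
    df = pd.read_csv(path, dtype={"protein": str, "motives": str})
    for col in ("protein", "direction", "motives"):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r}")
    if df["protein"].duplicated().any():
        dups = df.loc[df["protein"].duplicated(), "protein"].tolist()
        raise ValidationError(f"duplicate protein rows: {dups}")
    effectors = []
    for row in df.itertuples(index=False):
        direction = int(row.direction)
        if direction not in (+1, -1):
            raise ValidationError(
                f"direction for {row.protein} must be +1 or -1, got {direction}"
            )
        motives = frozenset(m.strip() for m in str(row.motives).split(";") if m.strip())
        effectors.append(Effector(protein=row.protein, direction=direction, motives=motives))
    anchor = None
    if "anchor" in df.columns:
        flagged = df.loc[df["anchor"].astype(bool), "protein"]
        if len(flagged):
            anchor = flagged.iloc[0]
    return DiseaseDefinition(effectors=effectors, anchor_stimulus=anchor)


def write_disease_definition(defn: DiseaseDefinition, path) -> None:
    rows = [
        {
            "protein": e.protein,
            "direction": e.direction,
            "motives": ";".join(sorted(e.motives)),
            "anchor": e.protein == defn.anchor_stimulus,
        }
        for e in defn.effectors
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_known_biomarkers(path) -> list[KnownBiomarker]:
    """Read a known-biomarker CSV: gene_symbol, uniprot, cv_accuracy, plasma."""
    df = pd.read_csv(path, comment="#")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            KnownBiomarker(
                gene_symbol=row.gene_symbol,
                uniprot=getattr(row, "uniprot", ""),
                cv_accuracy=float(row.cv_accuracy)
                if pd.notna(getattr(row, "cv_accuracy", None))
                else None,
                plasma_measurable=bool(row.plasma_measurable),
            )
        )
    return out
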