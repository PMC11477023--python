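"""Solution ensembles: virtual individuals with per-protein activities in [-1, 1]."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class Solution:
    """One sampled network configuration ("virtual individual")."""

    activities: dict[str, float]
    weight_seed: int | None = None
    satisfied_fraction: float | None = None

    def __post_init__(self):
        bad = {p: v for p, v in self.activities.items() if not -1 <= v <= 1}
        if bad:
            raise ValidationError(f"activities outside [-1,1]: {bad}")


@dataclass
class SolutionEnsemble:
    """Ordered stack of solutions sharing one protein index.

    The activity matrix is n_solutions × n_proteins; `provenance` echoes the
    sampling configuration and seeds for reproducibility.
    """

    protein_index: list[str]
    matrix: np.ndarray
    weight_seeds: list[int | None] = field(default_factory=list)
    satisfied_fractions: list[float | None] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("matrix must be 2-D (solutions × proteins)")
        if self.matrix.shape[1] != len(self.protein_index):
            raise ValidationError(
                f"matrix has {self.matrix.shape[1]} columns for "
                f"{len(self.protein_index)} proteins"
            )
        if np.any(np.abs(self.matrix) > 1 + 1e-12):
            raise ValidationError("activities must lie in [-1, 1]")
        if not self.weight_seeds:
            self.weight_seeds = [None] * self.n_solutions
        if not self.satisfied_fractions:
            self.satisfied_fractions = [None] * self.n_solutions
        self._col = {p: i for i, p in enumerate(self.protein_index)}

    @property
    def n_solutions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.matrix.shape[1]

    def column(self, protein: str) -> np.ndarray:
        return self.matrix[:, self._col[protein]]

    def columns(self, proteins: list[str]) -> np.ndarray:
        return self.matrix[:, [self._col[p] for p in proteins]]

    def has_protein(self, protein: str) -> bool:
        return protein in self._col

    def solution(self, i: int) -> Solution:
        return Solution(
            activities=dict(zip(self.protein_index, self.matrix[i])),
            weight_seed=self.weight_seeds[i],
            satisfied_fraction=self.satisfied_fractions[i],
        )

    def subset(self, indices) -> "SolutionEnsemble":
        idx = list(indices)
        return SolutionEnsemble(
            protein_index=list(self.protein_index),
            matrix=self.matrix[idx],
            weight_seeds=[self.weight_seeds[i] for i in idx],
            satisfied_fractions=[self.satisfied_fractions[i] for i in idx],
            provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.protein_index)

    def save(self, matrix_path, manifest_path=None) -> None:
        """Persist as a TSV matrix (rows=solutions) plus a JSON manifest."""
        self.to_frame().to_csv(matrix_path, sep="\t", index=False, float_format="%.10g")
        if manifest_path is not None:
            manifest = {
                "n_solutions": self.n_solutions,
                "n_proteins": self.n_proteins,
                "weight_seeds": self.weight_seeds,
                "satisfied_fractions": self.satisfied_fractions,
                "provenance": self.provenance,
            }
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, matrix_path, manifest_path=None) -> "SolutionEnsemble":
        df = pd.read_csv(matrix_path, sep="\t")
        seeds: list = []
        fracs: list = []
        prov: dict = {}
        if manifest_path is not None:
            with open(manifest_path) as fh:
                manifest = json.load(fh)
            seeds = manifest.get("weight_seeds", [])
            fracs = manifest.get("satisfied_fractions", [])
            prov = manifest.get("provenance", {})
        return cls(
            protein_index=list(df.columns),
            matrix=df.to_numpy(),
            weight_seeds=seeds,
            satisfied_fractions=fracs,
            provenance=prov,
        )
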