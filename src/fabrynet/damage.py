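"""Per-solution damage score (tSignal) and high/low cohort stratification.

tSignal summarizes how strongly a solution expresses the disease
definition: the mean, over the effectors the solution modulates, of the
product of predicted activity v_i and characterization direction y_i.
Under the default `agreement` convention a higher tSignal means the
stimulus induces more disease; the `printed-minus` convention negates the
sum, matching the published formula verbatim, and simply flips the cohort
orientation.
"""

from __future__ import annotations

import numpy as np

from .disease import DiseaseDefinition
from .ensemble import SolutionEnsemble
from .errors import ConfigError, UndefinedScoreError
from .propagation import MODULATION_EPSILON

SIGN_CONVENTIONS = ("agreement", "printed-minus")


def tsignal(
    activities: dict[str, float],
    defn: DiseaseDefinition,
    sign_convention: str = "agreement",
    epsilon: float = MODULATION_EPSILON,
) -> float:
    """Mean sign-weighted activity over the modulated effectors of one solution."""
    if sign_convention not in SIGN_CONVENTIONS:
        raise ConfigError(f"unknown sign convention {sign_convention!r}")
    total = 0.0
    n = 0
    for e in defn.effectors:
        v = activities.get(e.protein, 0.0)
        if abs(v) > epsilon:
            total += v * e.direction
            n += 1
    if n == 0:
        raise UndefinedScoreError("no effector modulated in this solution")
    value = total / n
    return -value if sign_convention == "printed-minus" else value


def tsignal_ensemble(
    ensemble: SolutionEnsemble,
    defn: DiseaseDefinition,
    sign_convention: str = "agreement",
    epsilon: float = MODULATION_EPSILON,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tSignal per solution.

    Returns (values, defined_mask); solutions with no modulated effector get
    NaN and a False mask entry — they are flagged rather than erroring so
    the caller can exclude them from stratification.
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise ConfigError(f"unknown sign convention {sign_convention!r}")
    eff = [e for e in defn.effectors if ensemble.has_protein(e.protein)]
    if not eff:
        raise UndefinedScoreError("no effector present in the ensemble")
    V = ensemble.columns([e.protein for e in eff])
    y = np.array([e.direction for e in eff], dtype=float)
    modulated = np.abs(V) > epsilon
    n = modulated.sum(axis=1)
    weighted = np.where(modulated, V * y, 0.0).sum(axis=1)
    defined = n > 0
    values = np.full(ensemble.n_solutions, np.nan)
    values[defined] = weighted[defined] / n[defined]
    if sign_convention == "printed-minus":
        values = -values
    return values, defined


def stratify(
    tsignals, q: float = 0.10
) -> tuple[list[int], list[int], bool]:
    """Split solutions into low- and high-damage cohorts of size floor(q·N).

    Returns (low_indices, high_indices, degenerate) where `degenerate` flags
    a tie spanning a cohort boundary (the index-ascending tie-break then
    decides membership deterministically). NaN scores (undefined tSignal)
    are excluded from both cohorts.
    """
    if not 0 < q < 0.5:
        raise ConfigError(f"q must be in (0, 0.5), got {q}")
    values = np.asarray(tsignals, dtype=float)
    valid = np.flatnonzero(~np.isnan(values))
    n = len(valid)
    m = int(np.floor(q * len(values)))
    if m < 1:
        raise ConfigError(f"q·N = {q * len(values):.3g} < 1: no cohort can be formed")
    if 2 * m > n:
        raise ConfigError("cohorts would overlap: too few defined tSignals")
    order = valid[np.argsort(values[valid], kind="stable")]
    low = order[:m]
    high = order[-m:]
    degenerate = bool(
        (n > m and values[order[m - 1]] == values[order[m]])
        or (n > m and values[order[-m]] == values[order[-m - 1]])
    )
    return sorted(int(i) for i in low), sorted(int(i) for i in high), degenerate


def damage_table(
    ensemble: SolutionEnsemble,
    defn: DiseaseDefinition,
    q: float = 0.10,
    sign_convention: str = "agreement",
):
    """Full damage table: per-solution tSignal plus cohort labels."""
    import pandas as pd

    values, defined = tsignal_ensemble(ensemble, defn, sign_convention)
    low, high, degenerate = stratify(values, q)
    cohort = np.array(["unassigned"] * ensemble.n_solutions, dtype=object)
    cohort[low] = "low"
    cohort[high] = "high"
    df = pd.DataFrame(
        {
            "solution_id": np.arange(ensemble.n_solutions),
            "tsignal": values,
            "cohort": cohort,
        }
    )
    df.attrs["degenerate_ties"] = degenerate
    df.attrs["n_undefined"] = int((~defined).sum())
    return df
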