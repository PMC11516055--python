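"""Post-docking rescoring: affinity unit conversions, top-fraction pooling
from two scorers, and the physicochemical / ring-size filters applied before
visual inspection.

Affinity conversions follow dG = RT ln(Ki) (negative for favorable binding,
so dG = -RT ln(10) * pKi) and pKi = -log10(Ki) with
R = 1.9872e-3 kcal/(mol K) and T defaulting to 303.15 K (the simulation
temperature). Candidate pooling takes the union of the top fraction by
predicted pKi (higher is better) and the top fraction by docking energy
(lower is better). Filters implement Lipinski/Veber bounds plus a
strained/macrocyclic ring exclusion; every comparison is strict, so a
molecule sitting exactly on a bound passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "AffinityValue",
    "convert_affinity",
    "CandidateRecord",
    "rank_and_pool",
    "apply_filters",
    "FORBIDDEN_RING_SIZES",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 303.15  # K

FORBIDDEN_RING_SIZES = (3, 4, 7)  # plus any ring larger than 12
MACROCYCLE_LIMIT = 12


@dataclass(frozen=True)
class AffinityValue:
    """One affinity in three mutually consistent representations."""

    Ki: float  # molar
    pKi: float
    dG: float  # kcal/mol
    T: float = DEFAULT_TEMPERATURE


def convert_affinity(value: float, from_unit: str,
                     T: float = DEFAULT_TEMPERATURE) -> AffinityValue:
    """Populate Ki (M), pKi and dG (kcal/mol) from any one of them."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if from_unit == "Ki_molar":
        if value <= 0:
            raise ValueError("Ki must be positive")
        ki = float(value)
    elif from_unit == "pKi":
        ki = 10.0 ** (-float(value))
    elif from_unit == "dG_kcal":
        ki = math.exp(float(value) / (GAS_CONSTANT_KCAL * T))
    else:
        raise ValueError(f"unknown unit {from_unit!r}")
    return AffinityValue(Ki=ki, pKi=-math.log10(ki),
                         dG=GAS_CONSTANT_KCAL * T * math.log(ki), T=T)


@dataclass
class CandidateRecord:
    """One docked molecule with descriptors and both scores."""

    mol_id: str
    hbd: int
    hba: int
    clogp: float
    rot_bonds: int
    psa: float  # A^2
    ring_sizes: tuple[int, ...] = ()
    score_model: Optional[float] = None  # predicted pKi, higher better
    score_dock: Optional[float] = None  # docking energy, lower better
    annotation: str = ""  # free-text visual-inspection note


def _records_frame(cands: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cands])


def rank_and_pool(cands: Sequence[CandidateRecord],
                  fraction: float = 0.10) -> set[str]:
    """Union of the two top-fraction sets (model pKi desc, docking energy asc).

    Each scorer keeps its top ceil(fraction * N) molecules; ties break
    deterministically by mol_id.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    for c in cands:
        if c.score_model is None:
            raise ValueError(f"{c.mol_id}: missing model score")
        if c.score_dock is None:
            raise ValueError(f"{c.mol_id}: missing docking score")
    n_keep = math.ceil(fraction * len(cands))
    by_model = sorted(cands, key=lambda c: (-c.score_model, c.mol_id))
    by_dock = sorted(cands, key=lambda c: (c.score_dock, c.mol_id))
    return {c.mol_id for c in by_model[:n_keep]} | {c.mol_id for c in by_dock[:n_keep]}


def _first_failure(c: CandidateRecord) -> Optional[str]:
    for name in ("hbd", "hba", "clogp", "rot_bonds", "psa"):
        if getattr(c, name) is None:
            raise ValueError(f"{c.mol_id}: missing descriptor {name}")
    if c.hbd > 5:
        return "hbd>5"
    if c.hba > 10:
        return "hba>10"
    if c.clogp > 5:
        return "clogp>5"
    if c.rot_bonds > 10:
        return "rot_bonds>10"
    if c.psa > 140:
        return "psa>140"
    for size in c.ring_sizes:
        if size in FORBIDDEN_RING_SIZES or size > MACROCYCLE_LIMIT:
            return f"forbidden ring size {size}"
    return None


def apply_filters(cands: Sequence[CandidateRecord]) -> tuple[list[CandidateRecord],
                                                             list[tuple[CandidateRecord, str]]]:
    """Split candidates into kept and (removed, first failing rule).

    Removal rules (all strict inequalities): hbd > 5, hba > 10, Clog P > 5,
    rotatable bonds > 10, PSA > 140 A^2, or any ring of size 3, 4, 7 or
    more than 12 atoms.
    """
    kept: list[CandidateRecord] = []
    removed: list[tuple[CandidateRecord, str]] = []
    for c in cands:
        reason = _first_failure(c)
        if reason is None:
            kept.append(c)
        else:
            removed.append((c, reason))
    return kept, removed


def screen_table(cands: Sequence[CandidateRecord], fraction: float = 0.10,
                 filter_first: bool = False) -> pd.DataFrame:
    """Ranked, pooled and filtered shortlist as a DataFrame.

    Default order pools the two scorers' top fractions and then filters
    (``filter_first=True`` swaps the two steps). The output carries ranks,
    percentiles, pool membership, and the removal reason where applicable.
    """
    cands = list(cands)
    n = len(cands)
    if n == 0:
        raise ValueError("no candidates")
    df = _records_frame(cands)
    df["rank_model"] = df["score_model"].rank(ascending=False, method="first").astype(int)
    df["rank_dock"] = df["score_dock"].rank(ascending=True, method="first").astype(int)
    df["percentile_model"] = df["rank_model"] / n
    df["percentile_dock"] = df["rank_dock"] / n

    if filter_first:
        kept, removed = apply_filters(cands)
        pool = rank_and_pool(kept, fraction) if kept else set()
    else:
        pool = rank_and_pool(cands, fraction)
        pooled = [c for c in cands if c.mol_id in pool]
        kept, removed = apply_filters(pooled)

    reasons = {c.mol_id: r for c, r in removed}
    df["in_pool"] = df["mol_id"].isin(pool)
    df["kept"] = df["mol_id"].isin({c.mol_id for c in kept})
    df["removal_reason"] = df["mol_id"].map(reasons).fillna("")
    return df.sort_values(["kept", "rank_model"], ascending=[False, True]).reset_index(drop=True)
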