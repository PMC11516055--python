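"""Trajectory analytics: ligand RMSD, per-atom RMSF, stability classes,
and per-residue interaction fractions.

The stability classifier follows the mean-ligand-RMSD regimes observed in
MD ensembles of protein-ligand complexes: a ligand that stays put
(mean RMSD < 3 A) marks a stable complex, one that wanders but remains in
the pocket (3-10 A) intermediate flexibility, and one that leaves the site
(> 10 A) an unstable complex. RMSD is the deviation from the frame-0
(crystal) pose; by default the complex is first superposed on the frame-0
pocket so global tumbling does not masquerade as ligand motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .featurize import FeaturizerConfig, select_pocket
from .structures import ComplexStructure, Trajectory, LIGAND

__all__ = [
    "rmsd",
    "rmsf",
    "StabilityResult",
    "ligand_stability",
    "InteractionCriteria",
    "interaction_fractions",
    "STABILITY_THRESHOLDS",
]

STABILITY_THRESHOLDS = (3.0, 10.0)  # A


def rmsd(frame: np.ndarray, reference: np.ndarray,
         subset: Optional[Sequence[int]] = None) -> float:
    """Root-mean-square deviation over ``subset`` atoms (no superposition)."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape or frame.ndim != 2 or frame.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ: {frame.shape} vs {reference.shape}")
    idx = np.arange(len(frame)) if subset is None else np.asarray(subset, dtype=int)
    if len(idx) == 0:
        raise ValueError("subset must be nonempty")
    d2 = np.sum((frame[idx] - reference[idx]) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def rmsf(traj: Trajectory, subset: Optional[Sequence[int]] = None) -> np.ndarray:
    """Per-atom fluctuation about the trajectory-mean position."""
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    coords = np.stack(traj.frames)  # (T, n, 3)
    idx = np.arange(coords.shape[1]) if subset is None else np.asarray(subset, dtype=int)
    sub = coords[:, idx, :]
    mean = sub.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def _kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                      fit_idx: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``target`` using the fit atoms."""
    from scipy.spatial.transform import Rotation

    mu_m = mobile[fit_idx].mean(axis=0)
    mu_t = target[fit_idx].mean(axis=0)
    rot, _ = Rotation.align_vectors(target[fit_idx] - mu_t, mobile[fit_idx] - mu_m)
    return rot.apply(mobile - mu_m) + mu_t


@dataclass
class StabilityResult:
    per_frame_rmsd: np.ndarray  # A, length n_frames
    mean_rmsd: float
    stability_class: str  # stable | intermediate | unstable
    thresholds: tuple[float, float] = STABILITY_THRESHOLDS


def classify_stability(mean_rmsd: float,
                       thresholds: tuple[float, float] = STABILITY_THRESHOLDS) -> str:
    """Exhaustive, mutually exclusive classes; the bounds belong to the middle."""
    lo, hi = thresholds
    if mean_rmsd < lo:
        return "stable"
    if mean_rmsd > hi:
        return "unstable"
    return "intermediate"


def ligand_stability(traj: Trajectory, align: bool = True,
                     featurizer: FeaturizerConfig = FeaturizerConfig(),
                     thresholds: tuple[float, float] = STABILITY_THRESHOLDS) -> StabilityResult:
    """Per-frame ligand RMSD against the frame-0 pose, and the mean's class.

    With ``align=True`` (default) every frame is first least-squares
    superposed on the frame-0 binding-pocket atoms (protein atoms near the
    ligand; all protein atoms when the pocket is empty), so the measured
    motion is ligand-relative-to-pocket. ``align=False`` compares raw
    coordinates.
    """
    if traj.n_frames < 2:
        raise ValueError("stability analysis needs at least 2 frames")
    ref = traj.frames[0]
    lig_idx = np.array(traj.reference.ligand_indices, dtype=int)
    fit_idx = None
    if align:
        pocket = sorted(select_pocket(traj.reference, featurizer))
        fit = pocket if len(pocket) >= 3 else traj.reference.protein_indices
        if len(fit) >= 3:
            fit_idx = np.array(fit, dtype=int)

    per_frame = []
    for f in traj.frames:
        moved = _kabsch_superpose(f, ref, fit_idx) if fit_idx is not None else f
        per_frame.append(rmsd(moved, ref, subset=lig_idx))
    per_frame = np.array(per_frame)
    mean = float(per_frame.mean())
    return StabilityResult(per_frame_rmsd=per_frame, mean_rmsd=mean,
                           stability_class=classify_stability(mean, thresholds),
                           thresholds=thresholds)


# ---------------------------------------------------------------------------
# interaction fractions


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric contact definitions (all distances in A, angles in degrees)."""

    hbond_distance: float = 3.5
    hbond_angle: float = 120.0  # heavy-atom surrogate angle X-D...A
    pipi_centroid_distance: float = 5.5
    hydrophobic_distance: float = 4.0


def _covalent_neighbors(cplx: ComplexStructure) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {a.index: set() for a in cplx.atoms}
    for i, j, _ in cplx.ligand_bonds:
        adj[i].add(j)
        adj[j].add(i)
    for i, j in cplx.protein_bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _aromatic_rings(cplx: ComplexStructure) -> list[list[int]]:
    """Cycles whose members are all aromatic-flagged."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(a.index for a in cplx.atoms)
    g.add_edges_from((i, j) for i, j, _ in cplx.ligand_bonds)
    g.add_edges_from(cplx.protein_bonds)
    rings = []
    for cyc in nx.cycle_basis(g):
        if all(cplx.atoms[k].is_aromatic for k in cyc):
            rings.append(sorted(cyc))
    return rings


def _residue_of(cplx: ComplexStructure, idx: int) -> str:
    rid = cplx.atoms[idx].residue_id
    return rid if rid is not None else f"res_{idx}"


def interaction_fractions(traj: Trajectory,
                          criteria: InteractionCriteria = InteractionCriteria()) -> pd.DataFrame:
    """Fraction of frames in which each (interaction type, residue) contact holds.

    Detected per frame: hydrogen bonds (donor N/O bearing >= 1 H vs acceptor
    N/O, distance and heavy-atom surrogate angle criteria), pi-pi stacking
    (aromatic ring centroid distance), and hydrophobic contacts (apolar
    carbon pairs, where apolar means not bonded to N or O). Returns columns
    interaction_type, partner (residue id), fraction.
    """
    ref = traj.reference
    adj = _covalent_neighbors(ref)
    lig = ref.ligand_indices
    prot = ref.protein_indices

    def is_polar(k: int) -> bool:
        return ref.atoms[k].element in ("N", "O")

    def is_donor(k: int) -> bool:
        return is_polar(k) and ref.atoms[k].hydrogen_count >= 1

    lig_rings = [r for r in _aromatic_rings(ref) if all(k in set(lig) for k in r)]
    prot_rings = [r for r in _aromatic_rings(ref) if all(k in set(prot) for k in r)]
    apolar_lig = [k for k in lig if ref.atoms[k].element == "C"
                  and not any(is_polar(nb) for nb in adj[k])]
    apolar_prot = [k for k in prot if ref.atoms[k].element == "C"
                   and not any(is_polar(nb) for nb in adj[k])]

    counts: dict[tuple[str, str], int] = {}

    def surrogate_angle_ok(xyz: np.ndarray, donor: int, acceptor: int) -> bool:
        neigh = [nb for nb in adj[donor] if ref.atoms[nb].element != "H"]
        if not neigh:
            return True
        v_da = xyz[acceptor] - xyz[donor]
        for nb in neigh:
            v_dx = xyz[nb] - xyz[donor]
            cosang = np.dot(v_dx, v_da) / (np.linalg.norm(v_dx) * np.linalg.norm(v_da))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= criteria.hbond_angle:
                return True
        return False

    for xyz in traj.frames:
        seen: set[tuple[str, str]] = set()
        # hydrogen bonds, both donor directions
        for a in lig:
            for b in prot:
                if np.linalg.norm(xyz[a] - xyz[b]) > criteria.hbond_distance:
                    continue
                ok = (is_donor(a) and is_polar(b) and surrogate_angle_ok(xyz, a, b)) or \
                     (is_donor(b) and is_polar(a) and surrogate_angle_ok(xyz, b, a))
                if ok:
                    seen.add(("hbond", _residue_of(ref, b)))
        # pi-pi stacking via ring centroids
        for lr in lig_rings:
            c_l = xyz[lr].mean(axis=0)
            for pr in prot_rings:
                c_p = xyz[pr].mean(axis=0)
                if np.linalg.norm(c_l - c_p) <= criteria.pipi_centroid_distance:
                    seen.add(("pipi", _residue_of(ref, pr[0])))
        # hydrophobic contacts
        for a in apolar_lig:
            for b in apolar_prot:
                if np.linalg.norm(xyz[a] - xyz[b]) <= criteria.hydrophobic_distance:
                    seen.add(("hydrophobic", _residue_of(ref, b)))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1

    rows = [
        {"interaction_type": t, "partner": res, "fraction": c / traj.n_frames}
        for (t, res), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["interaction_type", "partner", "fraction"])
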