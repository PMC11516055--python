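"""Deterministic synthetic fixtures: toy complexes, pseudo-trajectories,
labeled datasets with a known affinity function, and screening libraries.

These generators are statistical stand-ins for real structures and MD
output, not physics. Ligands are random connected, valence-respecting bond
graphs with ~1.5 A bond lengths; pocket atoms sit 3-5 A from the ligand
envelope. Pseudo-trajectories emulate the three mobility regimes seen in MD
ensembles: *stable* (isotropic Gaussian jitter about the initial pose),
*intermediate* (jitter plus a bounded excursion that parks the mean ligand
RMSD between 3 and 10 A), and *unstable* (jitter plus monotone drift that
carries the ligand out of the pocket, mean RMSD > 10 A). Dataset labels are
a fixed affine function of the protein-ligand contact count — a quantity no
transformer output feeds into — so recovery tests cannot be self-fulfilling.

Every generator is a pure function of its config: one seed, one output,
bit-for-bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .featurize import FeaturizerConfig
from .screen import CandidateRecord, FORBIDDEN_RING_SIZES
from .structures import AtomRecord, ComplexStructure, Trajectory, LIGAND, PROTEIN

__all__ = [
    "SynthConfig",
    "make_complex",
    "make_trajectory",
    "make_labeled_dataset",
    "make_screen_library",
    "contact_count",
    "LABEL_SLOPE",
    "LABEL_INTERCEPT",
]

MAX_VALENCE = {"C": 4, "N": 3, "O": 2}
LIGAND_ELEMENT_POOL = ("C", "C", "C", "N", "O")  # carbon-rich, like real ligands
POCKET_ELEMENT_POOL = ("C", "C", "C", "N", "O", "S")
BOND_LENGTH = 1.5  # A
CLASH_DISTANCE = 1.2  # A

#: the recorded ground-truth affinity function: pKi = a * contacts + b.
#: The slope maps the typical contact-count range of generated complexes
#: (roughly 10-60 pairs within 4 A) onto the 2-9 pKi band real affinity
#: data occupies.
LABEL_SLOPE = 0.1
LABEL_INTERCEPT = 2.0
CONTACT_CUTOFF = 4.0  # A


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs. The defaults mirror the emulated study conditions:
    100 snapshots per trajectory and mobility regimes whose mean ligand RMSD
    lands firmly inside the stable (<3 A), intermediate (3-10 A) and
    unstable (>10 A) bands."""

    seed: int = 0
    n_ligand_atoms: int = 8
    n_pocket_atoms: int = 12
    # labeled datasets draw per-complex sizes from these ranges (inclusive),
    # emulating the size heterogeneity of real complex collections
    ligand_size_range: tuple[int, int] = (5, 14)
    pocket_size_range: tuple[int, int] = (6, 24)
    mobility: str = "stable"
    jitter_sigma: float = 0.3  # A
    drift_rate: float = 0.5  # A/frame, unstable regime
    excursion_radius: float = 6.0  # A, intermediate regime plateau
    n_frames: int = 100
    label_fn: str = "contact_count_linear"
    label_noise_sigma: float = 0.0  # pKi

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_ligand_atoms < 1 or self.n_pocket_atoms < 0:
            raise ValueError("counts must be positive (pocket may be empty)")
        if self.mobility not in ("stable", "intermediate", "unstable"):
            raise ValueError(f"unknown mobility {self.mobility!r}")
        if self.label_fn not in ("contact_count_linear", "distance_weighted"):
            raise ValueError(f"unknown label_fn {self.label_fn!r}")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_complex(cfg: SynthConfig) -> ComplexStructure:
    """A toy pocket-ligand pair: connected ligand tree + shell of pocket atoms.

    Ligand atoms get elements whose valence can absorb one more bond while
    the tree is growing; leftover valence becomes the hydrogen count.
    Each pocket atom is its own residue, 3-5 A from a random ligand atom.
    """
    rng = np.random.default_rng(cfg.seed)
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, int]] = []
    degree: list[int] = []

    for k in range(cfg.n_ligand_atoms):
        el = str(rng.choice(LIGAND_ELEMENT_POOL))
        if k == 0:
            elements.append(el)
            coords.append(np.zeros(3))
            degree.append(0)
            continue
        # attach to an existing atom with free valence
        candidates = [i for i in range(k) if degree[i] < MAX_VALENCE[elements[i]]]
        if not candidates:
            raise ValueError("impossible valence request: no attachment point left")
        parent = int(rng.choice(candidates))
        for _ in range(200):
            pos = coords[parent] + BOND_LENGTH * _random_unit(rng)
            if all(np.linalg.norm(pos - c) >= CLASH_DISTANCE for c in coords):
                break
        else:
            pos = coords[parent] + BOND_LENGTH * _random_unit(rng)
        elements.append(el)
        coords.append(pos)
        degree.append(0)
        i, j = sorted((parent, k))
        bonds.append((i, j, 1))
        degree[parent] += 1
        degree[k] += 1

    atoms: list[AtomRecord] = []
    for k, (el, pos) in enumerate(zip(elements, coords)):
        atoms.append(AtomRecord(
            index=k, element=el, coords=pos, origin=LIGAND,
            hydrogen_count=MAX_VALENCE[el] - degree[k],
        ))

    lig_xyz = np.array(coords)
    n_lig = len(atoms)
    placed: list[np.ndarray] = []
    for k in range(cfg.n_pocket_atoms):
        el = str(rng.choice(POCKET_ELEMENT_POOL))
        for _ in range(500):
            anchor = lig_xyz[rng.integers(n_lig)]
            pos = anchor + rng.uniform(3.0, 5.0) * _random_unit(rng)
            near_lig = np.min(np.linalg.norm(lig_xyz - pos, axis=1))
            near_prot = min((np.linalg.norm(p - pos) for p in placed), default=np.inf)
            if near_lig >= 2.8 and near_prot >= 2.2:
                break
        placed.append(pos)
        atoms.append(AtomRecord(
            index=n_lig + k, element=el, coords=pos, origin=PROTEIN,
            residue_id=f"A:POC:{k + 1}",
            hydrogen_count=1 if el in ("N", "O") else 0,
        ))

    return ComplexStructure(atoms=atoms, ligand_bonds=set(bonds), protein_bonds=set())


def make_trajectory(base: ComplexStructure, cfg: SynthConfig) -> Trajectory:
    """Pseudo-trajectory in the requested mobility regime (frame 0 = base).

    Protein atoms only jitter; ligand atoms additionally follow the regime's
    rigid-body displacement (none / bounded excursion / monotone drift).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    base_xyz = base.coords
    lig = np.array(base.ligand_indices, dtype=int)
    direction = _random_unit(rng)
    frames = [base_xyz.copy()]
    for t in range(1, cfg.n_frames):
        f = base_xyz + rng.normal(0.0, cfg.jitter_sigma, size=base_xyz.shape)
        if cfg.mobility == "intermediate":
            # saturating excursion: ramps to excursion_radius within ~1/5 of the run
            d = cfg.excursion_radius * (1.0 - np.exp(-5.0 * t / cfg.n_frames))
            f[lig] += d * direction
        elif cfg.mobility == "unstable":
            f[lig] += cfg.drift_rate * t * direction
        frames.append(f)
    return Trajectory(reference=base, frames=frames)


def contact_count(cplx: ComplexStructure, cutoff: float = CONTACT_CUTOFF) -> int:
    """Number of protein-ligand atom pairs within ``cutoff``."""
    lig = cplx.ligand_indices
    prot = cplx.protein_indices
    if not prot:
        return 0
    xyz = cplx.coords
    d = np.linalg.norm(xyz[np.array(prot)][:, None, :] - xyz[np.array(lig)][None, :, :], axis=-1)
    return int(np.sum(d <= cutoff))


def _distance_weighted_signal(cplx: ComplexStructure) -> float:
    lig = cplx.ligand_indices
    prot = cplx.protein_indices
    if not prot:
        return 0.0
    xyz = cplx.coords
    d = np.linalg.norm(xyz[np.array(prot)][:, None, :] - xyz[np.array(lig)][None, :, :], axis=-1)
    return float(np.sum(np.exp(-d / 2.0)))


def true_label(cplx: ComplexStructure, cfg: SynthConfig) -> float:
    """The noiseless ground-truth pKi for a complex under the recorded function."""
    if cfg.label_fn == "contact_count_linear":
        signal = float(contact_count(cplx))
    else:
        signal = _distance_weighted_signal(cplx)
    return float(np.clip(LABEL_SLOPE * signal + LABEL_INTERCEPT, 0.0, 14.0))


def make_labeled_dataset(n_complexes: int, cfg: SynthConfig,
                         ecif_schema: Optional[list] = None):
    """Labeled trajectories with a known affinity function.

    Returns ``(trajectories, dataset)`` where every frame-graph of one
    trajectory shares the trajectory's label: pKi = a * contacts + b +
    N(0, label_noise_sigma), clipped to [0, 14], with (a, b) =
    (LABEL_SLOPE, LABEL_INTERCEPT) recorded in the dataset metadata.
    """
    from .train import build_dataset

    if n_complexes < 1:
        raise ValueError("need at least one complex")
    label_rng = np.random.default_rng(cfg.seed + 7919)
    size_rng = np.random.default_rng(cfg.seed + 104729)
    trajs: list[Trajectory] = []
    for k in range(n_complexes):
        lo_l, hi_l = cfg.ligand_size_range
        lo_p, hi_p = cfg.pocket_size_range
        sub = replace(cfg, seed=cfg.seed + 1000 * (k + 1),
                      n_ligand_atoms=int(size_rng.integers(lo_l, hi_l + 1)),
                      n_pocket_atoms=int(size_rng.integers(lo_p, hi_p + 1)))
        base = make_complex(sub)
        label = true_label(base, cfg)
        if cfg.label_noise_sigma > 0:
            label += label_rng.normal(0.0, cfg.label_noise_sigma)
        label = float(np.clip(label, 0.0, 14.0))
        traj = make_trajectory(base, sub) if cfg.n_frames > 1 else Trajectory(
            reference=base, frames=[base.coords])
        traj.label_pKi = label
        trajs.append(traj)
    ds = build_dataset(trajs, FeaturizerConfig(),
                       ids=[f"synth_{cfg.seed}_{k}" for k in range(n_complexes)],
                       ecif_schema=ecif_schema)
    ds.provenance = "synthetic"
    ds.metadata.update({
        "label_fn": cfg.label_fn, "slope": LABEL_SLOPE,
        "intercept": LABEL_INTERCEPT, "noise_sigma": cfg.label_noise_sigma,
        "contact_cutoff": CONTACT_CUTOFF,
    })
    return trajs, ds


# ---------------------------------------------------------------------------
# screening library


def make_screen_library(n: int, seed: int = 0) -> pd.DataFrame:
    """Descriptor table spanning both sides of every filter boundary.

    Row kinds cycle through: clean passers, one designed violation per rule
    (hbd, hba, clogp, rot_bonds, psa, small ring, macrocycle), and
    exact-boundary rows (hbd=5, hba=10, clogp=5, rot=10, psa=140, ring 12)
    that must be kept under the strict-inequality rules. The column
    ``designed_fail`` carries the constructed ground truth. Deterministic:
    same (n, seed) gives identical CSV bytes via :func:`library_to_csv`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    violations = ["hbd", "hba", "clogp", "rot_bonds", "psa", "ring_small", "ring_macro"]
    boundary_cycle = [
        dict(hbd=5), dict(hba=10), dict(clogp=5.0), dict(rot_bonds=10),
        dict(psa=140.0), dict(ring_sizes="6|12"),
    ]
    for k in range(n):
        base = dict(
            mol_id=f"mol{k:05d}",
            hbd=int(rng.integers(0, 5)),
            hba=int(rng.integers(0, 10)),
            clogp=round(float(rng.uniform(-1.0, 4.9)), 3),
            rot_bonds=int(rng.integers(0, 10)),
            psa=round(float(rng.uniform(20.0, 139.0)), 2),
            ring_sizes="5|6" if k % 2 else "6",
            score_model=round(float(rng.uniform(2.0, 11.0)), 4),
            score_dock=round(float(rng.uniform(-12.0, -4.0)), 4),
        )
        kind = k % 4
        if kind == 1:  # designed violation
            rule = violations[(k // 4) % len(violations)]
            if rule == "hbd":
                base["hbd"] = int(rng.integers(6, 12))
            elif rule == "hba":
                base["hba"] = int(rng.integers(11, 20))
            elif rule == "clogp":
                base["clogp"] = round(float(rng.uniform(5.1, 9.0)), 3)
            elif rule == "rot_bonds":
                base["rot_bonds"] = int(rng.integers(11, 20))
            elif rule == "psa":
                base["psa"] = round(float(rng.uniform(140.5, 250.0)), 2)
            elif rule == "ring_small":
                base["ring_sizes"] = f"{int(rng.choice(FORBIDDEN_RING_SIZES))}|6"
            else:
                base["ring_sizes"] = f"6|{int(rng.integers(13, 20))}"
            base["designed_fail"] = True
        elif kind == 3:  # exact-boundary row: must be kept
            base.update(boundary_cycle[(k // 4) % len(boundary_cycle)])
            base["designed_fail"] = False
        else:
            base["designed_fail"] = False
        rows.append(base)
    cols = ["mol_id", "hbd", "hba", "clogp", "rot_bonds", "psa", "ring_sizes",
            "score_model", "score_dock", "designed_fail"]
    return pd.DataFrame(rows)[cols]


def library_to_csv(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, float_format="%.4f")


def library_records(df: pd.DataFrame) -> list[CandidateRecord]:
    """Convert a library table to screening CandidateRecords."""
    out = []
    for row in df.itertuples(index=False):
        rings = tuple(int(s) for s in str(row.ring_sizes).split("|") if s)
        out.append(CandidateRecord(
            mol_id=row.mol_id, hbd=int(row.hbd), hba=int(row.hba),
            clogp=float(row.clogp), rot_bonds=int(row.rot_bonds),
            psa=float(row.psa), ring_sizes=rings,
            score_model=float(row.score_model), score_dock=float(row.score_dock),
        ))
    return out
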