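"""Protein-ligand complex and trajectory data model plus standard-format I/O.

A complex is one protein chain set plus one small-molecule ligand, reduced to
heavy atoms. Explicit hydrogens in the input are folded into a per-heavy-atom
hydrogen count, which later becomes a node feature. Ligand bonds are taken
verbatim from the SDF/MOL bond block; protein bonds are inferred from residue
templates with a covalent-radius distance fallback for nonstandard residues.

Units are Angstroms throughout; atom indices are 0-based and contiguous.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "Trajectory",
    "parse_complex",
    "parse_trajectory",
    "snapshot",
    "write_complex",
    "ComplexFormatError",
]

PROTEIN = "protein"
LIGAND = "ligand"

#: single-bond covalent radii (A), used for the distance-fallback bond rule
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
}

KNOWN_ELEMENTS = set(COVALENT_RADII) | {
    "Na", "K", "Mg", "Ca", "Zn", "Fe", "Mn", "Cu", "Co", "Ni",
}


class ComplexFormatError(ValueError):
    """Raised when an input file violates its format grammar or our contracts."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a complex.

    ``hydrogen_count`` is the number of explicit hydrogens that were bonded to
    this atom in the input before hydrogens were dropped.
    """

    index: int
    element: str
    coords: np.ndarray  # shape (3,), A
    origin: str  # "protein" | "ligand"
    residue_id: Optional[str] = None
    formal_charge: int = 0
    is_aromatic: bool = False
    hydrogen_count: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if self.element not in KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.index}: unrecognized element {self.element!r}")
        if self.origin not in (PROTEIN, LIGAND):
            raise ValueError(f"atom {self.index}: origin must be protein or ligand")


@dataclass
class ComplexStructure:
    """One protein + one ligand with coordinates, elements and bond graphs.

    ``ligand_bonds`` holds ``(i, j, order)`` with i < j over ligand atom
    indices; ``protein_bonds`` holds ``(i, j)`` with i < j. Each pair is
    stored once.
    """

    atoms: list[AtomRecord]
    ligand_bonds: set[tuple[int, int, int]] = field(default_factory=set)
    protein_bonds: set[tuple[int, int]] = field(default_factory=set)
    label_pKi: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for k, a in enumerate(self.atoms):
            if a.index != k:
                raise ValueError("atom indices must be contiguous and 0-based")
        for i, j, _ in self.ligand_bonds:
            if not (0 <= i < n and 0 <= j < n) or i >= j:
                raise ValueError(f"invalid ligand bond ({i},{j})")
        for i, j in self.protein_bonds:
            if not (0 <= i < n and 0 <= j < n) or i >= j:
                raise ValueError(f"invalid protein bond ({i},{j})")
        if not self.ligand_indices:
            raise ValueError("complex must contain at least one ligand atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def ligand_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.origin == LIGAND]

    @property
    def protein_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.origin == PROTEIN]

    def with_coords(self, coords: np.ndarray) -> "ComplexStructure":
        """Return a copy with every atom's coordinates replaced (topology kept)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3)")
        atoms = [replace(a, coords=coords[k]) for k, a in enumerate(self.atoms)]
        return ComplexStructure(
            atoms=atoms,
            ligand_bonds=set(self.ligand_bonds),
            protein_bonds=set(self.protein_bonds),
            label_pKi=self.label_pKi,
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames over the atom set of a reference complex.

    Frame 0 is the reference for deviation metrics unless a caller overrides
    it. All frames share the reference's topology.
    """

    reference: ComplexStructure
    frames: list[np.ndarray]  # each (n_atoms, 3)
    times: Optional[list[float]] = None  # ns
    label_pKi: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.reference.n_atoms
        checked = []
        for t, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {t}: expected {n} atoms, got {f.shape[0]}")
            checked.append(f)
        self.frames = checked

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def snapshot(traj: Trajectory, t: int) -> ComplexStructure:
    """Reference structure with coordinates of frame ``t``; topology unchanged."""
    if not (0 <= t < traj.n_frames):
        raise IndexError(f"frame {t} out of range [0, {traj.n_frames})")
    s = traj.reference.with_coords(traj.frames[t])
    s.label_pKi = traj.label_pKi if traj.label_pKi is not None else s.label_pKi
    return s


# ---------------------------------------------------------------------------
# parsing


def _parse_ligand(ligand_file) -> tuple[list[dict], list[tuple[int, int, int]]]:
    """Read an SDF/MOL V2000 ligand with RDKit, fold hydrogens into counts.

    Returns per-heavy-atom property dicts and the heavy-atom bond list.
    """
    from rdkit import Chem

    text = Path(ligand_file).read_text()
    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise ComplexFormatError(f"{ligand_file}: not a valid MOL/SDF V2000 block")
    if mol.GetNumBonds() == 0 and mol.GetNumAtoms() > 1:
        raise ComplexFormatError(
            f"{ligand_file}: bonds required — ligand file has no bond block"
        )
    if mol.GetNumAtoms() == 0:
        raise ComplexFormatError(f"{ligand_file}: empty ligand")
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        # keep raw perception if sanitization fails; aromatic flags come from file
        pass
    conf = mol.GetConformer()

    heavy = [a for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    if not heavy:
        raise ComplexFormatError(f"{ligand_file}: ligand has no heavy atoms")
    remap = {a.GetIdx(): k for k, a in enumerate(heavy)}
    atoms = []
    for a in heavy:
        h_explicit = sum(1 for nb in a.GetNeighbors() if nb.GetSymbol() == "H")
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            dict(
                element=a.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                formal_charge=a.GetFormalCharge(),
                is_aromatic=bool(a.GetIsAromatic()),
                hydrogen_count=h_explicit + a.GetNumImplicitHs(),
            )
        )
    bonds = []
    order_map = {
        Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: 12,
    }
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            i2, j2 = sorted((remap[i], remap[j]))
            bonds.append((i2, j2, order_map.get(b.GetBondType(), 1)))
    return atoms, bonds


def _parse_protein(protein_file) -> list[dict]:
    """Read protein heavy atoms from PDB via biotite, fold H into counts."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(protein_file))
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite reports the offending line
        raise ComplexFormatError(f"{protein_file}: {exc}") from exc

    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        return [], set()
    # infer bonds once on the full (H-containing) structure to count hydrogens
    try:
        bonds = struc.connect_via_residue_names(arr)
        if bonds.get_bond_count() == 0:
            bonds = struc.connect_via_distances(arr)
    except Exception:
        bonds = struc.connect_via_distances(arr)
    arr.bonds = bonds
    adj = [set() for _ in range(arr.array_length())]
    for i, j, _ in arr.bonds.as_array():
        adj[i].add(j)
        adj[j].add(i)

    elements = [e.capitalize() for e in arr.element]
    atoms = []
    for k in range(arr.array_length()):
        if elements[k] == "H":
            continue
        h_count = sum(1 for nb in adj[k] if elements[nb] == "H")
        atoms.append(
            dict(
                element=elements[k],
                coords=np.array(arr.coord[k], dtype=float),
                residue_id=f"{arr.chain_id[k]}:{arr.res_name[k]}:{arr.res_id[k]}",
                formal_charge=0,
                is_aromatic=False,
                hydrogen_count=h_count,
                _orig_index=k,
            )
        )
    # carry inferred heavy-heavy bonds through the heavy-atom renumbering
    heavy_remap = {a["_orig_index"]: i for i, a in enumerate(atoms)}
    heavy_bonds = set()
    for i, j, _ in arr.bonds.as_array():
        if i in heavy_remap and j in heavy_remap:
            heavy_bonds.add(tuple(sorted((heavy_remap[i], heavy_remap[j]))))
    for a in atoms:
        a.pop("_orig_index")
    return atoms, heavy_bonds


def infer_bonds_by_distance(elements: Sequence[str], coords: np.ndarray,
                            tolerance: float = 0.4) -> set[tuple[int, int]]:
    """Covalent-radius fallback: bond iff d < r_cov(i) + r_cov(j) + tolerance."""
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    out: set[tuple[int, int]] = set()
    for i in range(n):
        ri = COVALENT_RADII.get(elements[i])
        if ri is None:
            continue
        for j in range(i + 1, n):
            rj = COVALENT_RADII.get(elements[j])
            if rj is None:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < ri + rj + tolerance:
                out.add((i, j))
    return out


def parse_complex(protein_file, ligand_file, label_pKi: Optional[float] = None) -> ComplexStructure:
    """Build a :class:`ComplexStructure` from a protein PDB and a ligand SDF/MOL.

    Heavy atoms only; explicit hydrogens become per-atom hydrogen counts.
    Ligand bonds come verbatim from the file's bond block; protein bonds are
    inferred (residue templates, then a covalent-radius distance fallback).
    """
    lig_atoms, lig_bonds = _parse_ligand(ligand_file)
    prot_atoms, prot_heavy_bonds = _parse_protein(protein_file)

    atoms: list[AtomRecord] = []
    for a in lig_atoms:
        atoms.append(AtomRecord(index=len(atoms), origin=LIGAND, **a))
    n_lig = len(atoms)
    for a in prot_atoms:
        atoms.append(AtomRecord(index=len(atoms), origin=PROTEIN, **a))
    if not prot_heavy_bonds and prot_atoms:
        elems = [a["element"] for a in prot_atoms]
        xyz = np.array([a["coords"] for a in prot_atoms])
        prot_heavy_bonds = infer_bonds_by_distance(elems, xyz)
    protein_bonds = {(i + n_lig, j + n_lig) for i, j in prot_heavy_bonds}

    return ComplexStructure(
        atoms=atoms,
        ligand_bonds={(i, j, o) for i, j, o in lig_bonds},
        protein_bonds=protein_bonds,
        label_pKi=label_pKi,
    )


def parse_trajectory(reference: ComplexStructure, frames_file,
                     label_pKi: Optional[float] = None) -> Trajectory:
    """Read frames from a multi-model PDB or a TSV table (frame, atom, x, y, z).

    Frame order follows the file. The reference supplies topology; every
    frame must match its atom count.
    """
    path = Path(frames_file)
    text = path.read_text()
    if text.lstrip().split(None, 1)[0].lower() in ("frame", "0", "1") and "\t" in text:
        frames = _frames_from_table(text)
    elif "MODEL" in text or text.lstrip().startswith(("ATOM", "HETATM")):
        frames = _frames_from_multimodel_pdb(str(path))
    else:
        frames = _frames_from_table(text)
    n = reference.n_atoms
    for t, f in enumerate(frames):
        if f.shape[0] != n:
            raise ComplexFormatError(f"frame {t}: expected {n} atoms, got {f.shape[0]}")
    return Trajectory(reference=reference, frames=frames,
                      label_pKi=label_pKi if label_pKi is not None else reference.label_pKi)


def _frames_from_multimodel_pdb(path: str) -> list[np.ndarray]:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(path)
    arr = pdb_file.get_structure()  # AtomArrayStack
    if arr.stack_depth() == 0:
        raise ComplexFormatError(f"{path}: no models found")
    return [np.array(arr.coord[m], dtype=float) for m in range(arr.stack_depth())]


def _frames_from_table(text: str) -> list[np.ndarray]:
    """Plain-text dialect: whitespace-separated ``frame atom x y z`` rows."""
    import pandas as pd

    df = pd.read_csv(io.StringIO(text), sep=r"\s+")
    need = {"frame", "atom", "x", "y", "z"}
    if not need <= set(df.columns):
        raise ComplexFormatError(f"frame table needs columns {sorted(need)}")
    frames = []
    for t in sorted(df["frame"].unique()):
        sub = df[df["frame"] == t].sort_values("atom")
        frames.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    return frames


# ---------------------------------------------------------------------------
# writing


def write_complex(cplx: ComplexStructure, protein_file, ligand_file) -> None:
    """Write the protein part as PDB and the ligand part as MOL V2000."""
    _write_protein_pdb(cplx, protein_file)
    _write_ligand_mol(cplx, ligand_file)


def _write_protein_pdb(cplx: ComplexStructure, path) -> None:
    lines = []
    serial = 1
    for a in cplx.atoms:
        if a.origin != PROTEIN:
            continue
        chain, res_name, res_id = "A", "UNK", 1
        if a.residue_id and a.residue_id.count(":") == 2:
            chain, res_name, res_id_s = a.residue_id.split(":")
            res_id = int(res_id_s)
        x, y, z = a.coords
        name = f"{a.element}{serial % 100}"[:4]
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{res_name:>4s} {chain}{res_id:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_ligand_mol(cplx: ComplexStructure, path) -> None:
    lig = cplx.ligand_indices
    remap = {gi: k for k, gi in enumerate(lig)}
    bonds = sorted((remap[i], remap[j], o) for i, j, o in cplx.ligand_bonds)
    lines = ["ligand", "  dynabind", ""]
    lines.append(f"{len(lig):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    charge_lines = []
    for k, gi in enumerate(lig):
        a = cplx.atoms[gi]
        x, y, z = a.coords
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        if a.formal_charge:
            charge_lines.append((k + 1, a.formal_charge))
    for i, j, o in bonds:
        mol_order = 4 if o == 12 else o
        lines.append(f"{i + 1:3d}{j + 1:3d}{mol_order:3d}  0  0  0  0")
    for k, q in charge_lines:
        lines.append(f"M  CHG  1 {k:3d} {q:3d}")
    lines.append("M  END")
    lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON serialization of the normalized data model (CLI interchange format)


def complex_to_json(cplx: ComplexStructure) -> dict:
    return {
        "format_version": 1,
        "atoms": [
            {
                "index": a.index, "element": a.element,
                "coords": [float(v) for v in a.coords], "origin": a.origin,
                "residue_id": a.residue_id, "formal_charge": a.formal_charge,
                "is_aromatic": a.is_aromatic, "hydrogen_count": a.hydrogen_count,
            }
            for a in cplx.atoms
        ],
        "ligand_bonds": sorted([list(b) for b in cplx.ligand_bonds]),
        "protein_bonds": sorted([list(b) for b in cplx.protein_bonds]),
        "label_pKi": cplx.label_pKi,
    }


def complex_from_json(obj: dict) -> ComplexStructure:
    atoms = [
        AtomRecord(
            index=a["index"], element=a["element"],
            coords=np.array(a["coords"], dtype=float), origin=a["origin"],
            residue_id=a.get("residue_id"), formal_charge=a.get("formal_charge", 0),
            is_aromatic=a.get("is_aromatic", False),
            hydrogen_count=a.get("hydrogen_count", 0),
        )
        for a in obj["atoms"]
    ]
    return ComplexStructure(
        atoms=atoms,
        ligand_bonds={tuple(b) for b in obj.get("ligand_bonds", [])},
        protein_bonds={tuple(b) for b in obj.get("protein_bonds", [])},
        label_pKi=obj.get("label_pKi"),
    )
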