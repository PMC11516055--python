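"""Rigid-motion and relabeling helpers for the acceptance computations."""

from __future__ import annotations

import numpy as np

from dynabind.featurize import FeaturizerConfig, build_graph
from dynabind.fingerprints import build_ecif_schema, default_fingerprints
from dynabind.structures import AtomRecord, ComplexStructure


def featurize_pair(cplx: ComplexStructure, schema=None):
    if schema is None:
        schema = build_ecif_schema([cplx])
    g = build_graph(cplx, FeaturizerConfig())
    fps = default_fingerprints(cplx, ecif_schema=schema)
    return g, fps, schema


def rigid(cplx: ComplexStructure, rng: np.random.Generator) -> ComplexStructure:
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    return cplx.with_coords(cplx.coords @ rot.T + shift)


def perm_complex(cplx: ComplexStructure, rng: np.random.Generator) -> ComplexStructure:
    perm = rng.permutation(cplx.n_atoms)
    inv = np.argsort(perm)
    atoms = []
    for new_idx, old_idx in enumerate(perm):
        a = cplx.atoms[old_idx]
        atoms.append(AtomRecord(
            index=new_idx, element=a.element, coords=a.coords, origin=a.origin,
            residue_id=a.residue_id, formal_charge=a.formal_charge,
            is_aromatic=a.is_aromatic, hydrogen_count=a.hydrogen_count))
    lig_bonds = {(min(int(inv[i]), int(inv[j])), max(int(inv[i]), int(inv[j])), o)
                 for i, j, o in cplx.ligand_bonds}
    prot_bonds = {(min(int(inv[i]), int(inv[j])), max(int(inv[i]), int(inv[j])))
                  for i, j in cplx.protein_bonds}
    return ComplexStructure(atoms=atoms, ligand_bonds=lig_bonds,
                            protein_bonds=prot_bonds, label_pKi=cplx.label_pKi)
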