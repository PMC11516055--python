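"""Shared fixtures: small synthetic complexes, graphs and tiny networks."""

from __future__ import annotations

import numpy as np
import pytest

from dynabind.featurize import FeaturizerConfig, build_graph
from dynabind.fingerprints import build_ecif_schema, default_fingerprints
from dynabind.model import DynaformerNet, ModelConfig
from dynabind.structures import AtomRecord, ComplexStructure
from dynabind.synthgen import SynthConfig, make_complex


def tiny_model_config(fp_dims, seed: int = 0) -> ModelConfig:
    return ModelConfig(n_layers=2, hidden_dim=32, n_heads=4, K_gbf=16,
                       fingerprint_dims=tuple(fp_dims), seed=seed)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation plus a translation of up to 20 A."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    return lambda xyz: xyz @ rot.T + shift


def transformed(cplx: ComplexStructure, transform) -> ComplexStructure:
    return cplx.with_coords(transform(cplx.coords))


def permuted(cplx: ComplexStructure, perm: np.ndarray) -> ComplexStructure:
    """Relabel atoms by ``perm`` (new index k holds old atom perm[k])."""
    inv = np.argsort(perm)
    atoms = []
    for new_idx, old_idx in enumerate(perm):
        a = cplx.atoms[old_idx]
        atoms.append(AtomRecord(
            index=new_idx, element=a.element, coords=a.coords, origin=a.origin,
            residue_id=a.residue_id, formal_charge=a.formal_charge,
            is_aromatic=a.is_aromatic, hydrogen_count=a.hydrogen_count,
        ))
    lig_bonds = set()
    for i, j, o in cplx.ligand_bonds:
        ni, nj = sorted((int(inv[i]), int(inv[j])))
        lig_bonds.add((ni, nj, o))
    prot_bonds = set()
    for i, j in cplx.protein_bonds:
        ni, nj = sorted((int(inv[i]), int(inv[j])))
        prot_bonds.add((ni, nj))
    return ComplexStructure(atoms=atoms, ligand_bonds=lig_bonds,
                            protein_bonds=prot_bonds, label_pKi=cplx.label_pKi)


@pytest.fixture(scope="session")
def toy_complex() -> ComplexStructure:
    return make_complex(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def toy_graph(toy_complex):
    return build_graph(toy_complex, FeaturizerConfig())


@pytest.fixture(scope="session")
def toy_fps(toy_complex):
    schema = build_ecif_schema([toy_complex])
    return default_fingerprints(toy_complex, ecif_schema=schema)


@pytest.fixture(scope="session")
def tiny_net(toy_fps) -> DynaformerNet:
    return DynaformerNet(tiny_model_config([len(f.values) for f in toy_fps]))
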