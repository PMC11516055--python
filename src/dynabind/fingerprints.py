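"""Knowledge-based protein-ligand interaction fingerprints.

Three families of fixed-length descriptors are fused into the prediction
head, covering interactions beyond the graph's distance cutoff:

* ``rfscore`` — occurrence counts of protein-ligand element pairs within a
  12 A cutoff, over protein elements {C, N, O, S} x ligand elements
  {C, N, O, F, P, S, Cl, Br, I} (36 entries).
* ``ecif`` — counts of typed-atom pairs within 6 A, where an atom type is
  (element; heavy-neighbor count; attached-H count; aromaticity; ring
  membership; explicit valence). The type vocabulary is data-driven and
  persisted as a schema so vectors are only compared under one schema.
* ``gbscore`` — distance-weighted element-pair features: per element pair
  and Gaussian shell (mu, sigma), the sum over pairs of
  exp(-(r - mu)^2 / (2 sigma^2)).

All three depend only on interatomic distances and topology, hence are
invariant to rigid transforms and atom reordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structures import ComplexStructure, LIGAND, PROTEIN

__all__ = [
    "FingerprintVector",
    "rfscore_fp",
    "ecif_like_fp",
    "gbscore_like_fp",
    "default_fingerprints",
    "DEFAULT_SHELLS",
]

PROTEIN_ELEMENTS = ("C", "N", "O", "S")
LIGAND_ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

#: default Gaussian shells for the gbscore family: centers spanning the
#: contact range 2-12 A with 1 A width
DEFAULT_SHELLS: tuple[tuple[float, float], ...] = tuple(
    (float(mu), 1.0) for mu in (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
)


@dataclass
class FingerprintVector:
    family: str  # "rfscore" | "ecif" | "gbscore"
    values: np.ndarray
    schema_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("fingerprint values must be a 1-D vector")


def _pair_distances(cplx: ComplexStructure) -> tuple[list[int], list[int], np.ndarray]:
    prot = cplx.protein_indices
    lig = cplx.ligand_indices
    xyz = cplx.coords
    if not prot:
        return prot, lig, np.zeros((0, len(lig)))
    d = np.linalg.norm(xyz[np.array(prot)][:, None, :] - xyz[np.array(lig)][None, :, :], axis=-1)
    return prot, lig, d


def rfscore_fp(cplx: ComplexStructure, cutoff: float = 12.0) -> FingerprintVector:
    """Element-pair occurrence counts within ``cutoff`` (36-vector)."""
    prot, lig, d = _pair_distances(cplx)
    counts = np.zeros((len(PROTEIN_ELEMENTS), len(LIGAND_ELEMENTS)))
    pe = {e: k for k, e in enumerate(PROTEIN_ELEMENTS)}
    le = {e: k for k, e in enumerate(LIGAND_ELEMENTS)}
    for a, p_idx in enumerate(prot):
        ep = cplx.atoms[p_idx].element
        if ep not in pe:
            continue
        for b, l_idx in enumerate(lig):
            el = cplx.atoms[l_idx].element
            if el not in le:
                continue
            if d[a, b] <= cutoff:
                counts[pe[ep], le[el]] += 1
    return FingerprintVector(
        family="rfscore", values=counts.ravel(),
        schema_id=f"rfscore:4x9:cutoff={cutoff:g}",
    )


def _atom_type(cplx: ComplexStructure, idx: int) -> tuple:
    """ECIF-style atom environment: element plus local topology descriptors."""
    a = cplx.atoms[idx]
    heavy_neighbors = 0
    valence = 0
    for i, j, o in cplx.ligand_bonds:
        if idx in (i, j):
            heavy_neighbors += 1
            valence += 2 if o == 2 else 3 if o == 3 else 1
    for i, j in cplx.protein_bonds:
        if idx in (i, j):
            heavy_neighbors += 1
            valence += 1
    valence += a.hydrogen_count
    in_ring = _in_ring(cplx, idx)
    return (a.element, heavy_neighbors, a.hydrogen_count,
            int(a.is_aromatic), int(in_ring), valence)


def _in_ring(cplx: ComplexStructure, idx: int) -> bool:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(a.index for a in cplx.atoms)
    g.add_edges_from((i, j) for i, j, _ in cplx.ligand_bonds)
    g.add_edges_from(cplx.protein_bonds)
    for cyc in nx.cycle_basis(g):
        if idx in cyc:
            return True
    return False


def ecif_like_fp(cplx: ComplexStructure, cutoff: float = 6.0,
                 schema: Optional[list[tuple]] = None) -> FingerprintVector:
    """Typed-atom-pair counts within ``cutoff``.

    Without a ``schema`` the observed (protein type, ligand type) pairs are
    enumerated in canonical sorted order and persisted in ``schema_id``; pass
    a schema to project a new structure onto an existing vocabulary.
    """
    if not cplx.ligand_bonds and len(cplx.ligand_indices) > 1:
        raise ValueError("ligand bond graph required for typed-atom environments")
    prot, lig, d = _pair_distances(cplx)
    p_types = {p: _atom_type(cplx, p) for p in prot}
    l_types = {l: _atom_type(cplx, l) for l in lig}

    pair_counts: dict[tuple, int] = {}
    for a, p_idx in enumerate(prot):
        for b, l_idx in enumerate(lig):
            if d[a, b] <= cutoff:
                key = (p_types[p_idx], l_types[l_idx])
                pair_counts[key] = pair_counts.get(key, 0) + 1

    if schema is None:
        schema = sorted(pair_counts)
    values = np.array([pair_counts.get(key, 0) for key in schema], dtype=float)
    schema_repr = ";".join(repr(k) for k in schema)
    return FingerprintVector(
        family="ecif",
        values=values,
        schema_id=f"ecif:cutoff={cutoff:g}:n={len(schema)}:{hash(schema_repr) & 0xFFFFFFFF:08x}",
    )


def gbscore_like_fp(cplx: ComplexStructure,
                    shells: Sequence[tuple[float, float]] = DEFAULT_SHELLS) -> FingerprintVector:
    """Gaussian-shell distance-weighted element-pair features (36 x n_shells)."""
    if len(shells) == 0:
        raise ValueError("at least one (mu, sigma) shell required")
    for mu, sigma in shells:
        if sigma <= 0:
            raise ValueError(f"shell sigma must be positive, got {sigma}")
    prot, lig, d = _pair_distances(cplx)
    pe = {e: k for k, e in enumerate(PROTEIN_ELEMENTS)}
    le = {e: k for k, e in enumerate(LIGAND_ELEMENTS)}
    out = np.zeros((len(PROTEIN_ELEMENTS), len(LIGAND_ELEMENTS), len(shells)))
    for a, p_idx in enumerate(prot):
        ep = cplx.atoms[p_idx].element
        if ep not in pe:
            continue
        for b, l_idx in enumerate(lig):
            el = cplx.atoms[l_idx].element
            if el not in le:
                continue
            r = d[a, b]
            for s, (mu, sigma) in enumerate(shells):
                out[pe[ep], le[el], s] += np.exp(-((r - mu) ** 2) / (2 * sigma ** 2))
    sid = "gbscore:" + ",".join(f"{mu:g}/{sigma:g}" for mu, sigma in shells)
    return FingerprintVector(family="gbscore", values=out.ravel(), schema_id=sid)


def build_ecif_schema(cplxs: Sequence[ComplexStructure], cutoff: float = 6.0) -> list[tuple]:
    """Union of observed typed-atom pairs over a dataset, canonically sorted.

    Training pipelines call this once so every complex shares one ECIF
    vocabulary (and therefore one vector length).
    """
    seen: set[tuple] = set()
    for c in cplxs:
        prot, lig, d = _pair_distances(c)
        p_types = {p: _atom_type(c, p) for p in prot}
        l_types = {l: _atom_type(c, l) for l in lig}
        for a, p_idx in enumerate(prot):
            for b, l_idx in enumerate(lig):
                if d[a, b] <= cutoff:
                    seen.add((p_types[p_idx], l_types[l_idx]))
    return sorted(seen)


def default_fingerprints(cplx: ComplexStructure,
                         ecif_schema: Optional[list[tuple]] = None) -> list[FingerprintVector]:
    """The three default-family fingerprints for one structure, in fixed order."""
    return [
        ecif_like_fp(cplx, schema=ecif_schema),
        rfscore_fp(cplx),
        gbscore_like_fp(cplx),
    ]
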