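"""Graph construction: pocket selection, typed edges, shortest paths, angles.

A complex becomes a graph G = (V, E). V holds one coordinate-free virtual
node (global readout) plus every ligand heavy atom plus the protein heavy
atoms within the pocket cutoff d_p of any ligand atom. Edges are covalent
(from the bond graphs) or non-covalent (any remaining pair within d_s).
Every quantity attached to the graph — pairwise distances, shortest-path edge
sequences, angle sums over bonded triplets — is a function of interatomic
distances and topology only, so the representation is invariant to rigid
rotations and translations of the input coordinates.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structures import ComplexStructure, LIGAND, PROTEIN

__all__ = [
    "FeaturizerConfig",
    "NodeFeatures",
    "EdgeRecord",
    "ComplexGraph",
    "select_pocket",
    "build_graph",
    "shortest_paths",
    "angle_sums",
]

# fixed categorical vocabularies; index 0 of each embedding table is reserved
# for the virtual node
ELEMENT_VOCAB = ["*", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Se", "other"]
HYBRIDIZATION_VOCAB = ["*", "unspecified", "sp", "sp2", "sp3", "other"]
CHIRALITY_VOCAB = ["*", "none", "cw", "ccw", "other"]
BOND_ORDER_VOCAB = ["noncovalent", "single", "double", "triple", "aromatic", "other"]

MAX_DEGREE = 10
MAX_HCOUNT = 8
MAX_CHARGE = 5  # formal charge clipped to [-5, 5]

VIRTUAL = 0  # reserved categorical code


@dataclass(frozen=True)
class FeaturizerConfig:
    """Cutoffs controlling the graph.

    d_p : pocket cutoff (A) — protein atoms within this distance of any
        ligand atom are kept.
    d_s : non-covalent edge cutoff (A).
    P_max : cap on shortest-path length used by the path attention bias.
    cutoff_inclusive : whether "within d" means <= d (default) or < d.
    """

    d_p: float = 5.0
    d_s: float = 5.0
    P_max: int = 5
    cutoff_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.d_p <= 0 or self.d_s <= 0 or self.P_max < 1:
            raise ValueError("require d_p > 0, d_s > 0, P_max >= 1")

    def within(self, r: float, cutoff: float) -> bool:
        return r <= cutoff if self.cutoff_inclusive else r < cutoff


@dataclass(frozen=True)
class NodeFeatures:
    """Categorical node feature codes (integers into the vocabularies above)."""

    element: int
    degree: int
    formal_charge: int  # shifted code: charge + MAX_CHARGE + 1; 0 reserved
    hydrogen_count: int
    hybridization: int
    is_aromatic: int
    in_ring: int
    chirality: int
    origin: int  # 0 virtual, 1 ligand, 2 protein
    is_virtual: bool

    def as_codes(self) -> tuple[int, ...]:
        return (
            self.element, self.degree, self.formal_charge, self.hydrogen_count,
            self.hybridization, self.is_aromatic, self.in_ring, self.chirality,
            self.origin,
        )


@dataclass(frozen=True)
class EdgeRecord:
    i: int
    j: int
    kind: str  # "covalent" | "noncovalent"
    bond_order: int  # code into BOND_ORDER_VOCAB (0 for noncovalent)
    conjugated: int
    in_ring: int
    distance: float  # A

    def as_codes(self) -> tuple[int, ...]:
        return (self.bond_order, self.conjugated, self.in_ring,
                0 if self.kind == "covalent" else 1)


@dataclass
class ComplexGraph:
    """Model input: virtual node + ligand + pocket atoms with typed edges.

    ``sp_paths[(i, j)]`` is the edge-index sequence of one shortest path
    (deterministic lowest-index tie-break), empty when the pair is
    disconnected or farther apart than ``P_max``. ``angle_sum[(i, j)]`` is
    the summed bond angle (degrees) at vertex j over covalent neighbors k of
    j, stored for covalently bonded ordered pairs; pairs without an entry
    read as 0.
    """

    nodes: list[NodeFeatures]
    coords: np.ndarray  # (n, 3); row 0 (virtual node) is NaN
    edges: list[EdgeRecord]
    sp_paths: dict[tuple[int, int], list[int]]
    angle_sum: dict[tuple[int, int], float]
    label_pKi: Optional[float] = None
    atom_index: Optional[list[int]] = None  # graph node -> source atom index

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))


def select_pocket(cplx: ComplexStructure, cfg: FeaturizerConfig = FeaturizerConfig()) -> set[int]:
    """Protein atoms whose minimum distance to any ligand atom is within d_p."""
    lig = cplx.ligand_indices
    prot = cplx.protein_indices
    if not lig:
        raise ValueError("complex has no ligand atoms")
    if not prot:
        return set()
    xyz = cplx.coords
    d = np.linalg.norm(xyz[np.array(prot)][:, None, :] - xyz[np.array(lig)][None, :, :], axis=-1)
    dmin = d.min(axis=1)
    if cfg.cutoff_inclusive:
        keep = {p for p, dm in zip(prot, dmin) if dm <= cfg.d_p}
    else:
        keep = {p for p, dm in zip(prot, dmin) if dm < cfg.d_p}
    if not keep:
        warnings.warn("pocket selection returned no protein atoms", stacklevel=2)
    return keep


def _covalent_adjacency(cplx: ComplexStructure) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {a.index: set() for a in cplx.atoms}
    for i, j, _ in cplx.ligand_bonds:
        adj[i].add(j)
        adj[j].add(i)
    for i, j in cplx.protein_bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _ring_membership(cplx: ComplexStructure) -> set[int]:
    """Atoms on any cycle of the full covalent graph (pre-truncation)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(a.index for a in cplx.atoms)
    g.add_edges_from((i, j) for i, j, _ in cplx.ligand_bonds)
    g.add_edges_from(cplx.protein_bonds)
    in_ring: set[int] = set()
    for cyc in nx.cycle_basis(g):
        in_ring.update(cyc)
    return in_ring


def _hybridization_code(cplx: ComplexStructure, idx: int, degree: int) -> int:
    """Coarse hybridization from heavy degree + hydrogen count + aromaticity."""
    a = cplx.atoms[idx]
    total = degree + a.hydrogen_count
    if a.is_aromatic:
        return HYBRIDIZATION_VOCAB.index("sp2")
    if a.element in ("C", "N", "O", "P", "S"):
        if total >= 4:
            return HYBRIDIZATION_VOCAB.index("sp3")
        orders = [o for i, j, o in cplx.ligand_bonds if idx in (i, j)]
        if any(o == 3 for o in orders):
            return HYBRIDIZATION_VOCAB.index("sp")
        if any(o in (2, 12) for o in orders):
            return HYBRIDIZATION_VOCAB.index("sp2")
        return HYBRIDIZATION_VOCAB.index("sp3")
    return HYBRIDIZATION_VOCAB.index("unspecified")


def _node_features(cplx: ComplexStructure, idx: int, adj: dict[int, set[int]],
                   rings: set[int]) -> NodeFeatures:
    a = cplx.atoms[idx]
    el = ELEMENT_VOCAB.index(a.element) if a.element in ELEMENT_VOCAB else ELEMENT_VOCAB.index("other")
    degree = min(len(adj[idx]), MAX_DEGREE)
    charge = int(np.clip(a.formal_charge, -MAX_CHARGE, MAX_CHARGE)) + MAX_CHARGE + 1
    return NodeFeatures(
        element=el,
        degree=degree + 1,  # shift: 0 reserved for virtual
        formal_charge=charge,
        hydrogen_count=min(a.hydrogen_count, MAX_HCOUNT) + 1,
        hybridization=_hybridization_code(cplx, idx, degree),
        is_aromatic=2 if a.is_aromatic else 1,
        in_ring=2 if idx in rings else 1,
        chirality=CHIRALITY_VOCAB.index("none"),
        origin=1 if a.origin == LIGAND else 2,
        is_virtual=False,
    )


_VIRTUAL_NODE = NodeFeatures(
    element=VIRTUAL, degree=VIRTUAL, formal_charge=VIRTUAL, hydrogen_count=VIRTUAL,
    hybridization=VIRTUAL, is_aromatic=VIRTUAL, in_ring=VIRTUAL, chirality=VIRTUAL,
    origin=VIRTUAL, is_virtual=True,
)


def build_graph(cplx: ComplexStructure, cfg: FeaturizerConfig = FeaturizerConfig()) -> ComplexGraph:
    """Featurize one complex (crystal pose or MD snapshot) into a ComplexGraph.

    Node topological features (degree, ring, aromaticity, hybridization) are
    computed on the full molecules before pocket truncation, so clipping the
    protein does not corrupt the chemistry of boundary atoms.
    """
    pocket = select_pocket(cplx, cfg)
    adj = _covalent_adjacency(cplx)
    rings = _ring_membership(cplx)

    kept = sorted(cplx.ligand_indices) + sorted(pocket)
    remap = {atom_idx: k + 1 for k, atom_idx in enumerate(kept)}  # node 0 is virtual

    nodes = [_VIRTUAL_NODE] + [_node_features(cplx, idx, adj, rings) for idx in kept]
    coords = np.full((len(nodes), 3), np.nan)
    xyz = cplx.coords
    for atom_idx, node in remap.items():
        coords[node] = xyz[atom_idx]

    # covalent edges restricted to kept atoms
    edges: list[EdgeRecord] = []
    covalent_pairs: set[tuple[int, int]] = set()
    bond_orders = {}
    for i, j, o in cplx.ligand_bonds:
        bond_orders[(i, j)] = o
    for i, j in cplx.protein_bonds:
        bond_orders[(i, j)] = 1
    order_code = {1: 1, 2: 2, 3: 3, 12: 4}
    for (i, j), o in sorted(bond_orders.items()):
        if i in remap and j in remap:
            ni, nj = remap[i], remap[j]
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            edges.append(EdgeRecord(
                i=ni, j=nj, kind="covalent",
                bond_order=order_code.get(o, BOND_ORDER_VOCAB.index("other")),
                conjugated=2 if o == 12 else 1,
                in_ring=2 if (i in rings and j in rings) else 1,
                distance=r,
            ))
            covalent_pairs.add((min(ni, nj), max(ni, nj)))

    # non-covalent edges: any remaining kept pair within d_s
    nk = len(kept)
    kept_arr = np.array(kept)
    sub = xyz[kept_arr]
    dist = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
    for a in range(nk):
        for b in range(a + 1, nk):
            ni, nj = a + 1, b + 1
            if (ni, nj) in covalent_pairs:
                continue
            r = float(dist[a, b])
            if cfg.within(r, cfg.d_s):
                edges.append(EdgeRecord(i=ni, j=nj, kind="noncovalent",
                                        bond_order=0, conjugated=1, in_ring=1,
                                        distance=r))

    g = ComplexGraph(nodes=nodes, coords=coords, edges=edges, sp_paths={},
                     angle_sum={}, label_pKi=cplx.label_pKi, atom_index=[-1] + kept)
    g.sp_paths = shortest_paths(g, cfg.P_max)
    g.angle_sum = angle_sums(g)
    return g


def shortest_paths(g: ComplexGraph, P_max: int) -> dict[tuple[int, int], list[int]]:
    """One BFS shortest path per ordered node pair, capped at ``P_max`` edges.

    The virtual node takes no part. Among the hop-shortest paths, the one
    with the smallest cumulative geometric length is chosen (an invariant of
    atom relabeling and rigid motion, so the selected path — and therefore
    the model's path bias — does not depend on input order); exact geometric
    ties fall back to the lowest-index predecessor. Pairs that are
    disconnected or farther than ``P_max`` get no entry (their path bias
    reads as 0).
    """
    n = g.n_nodes
    nbrs: dict[int, list[tuple[int, int]]] = {v: [] for v in range(1, n)}
    for e_idx, e in enumerate(g.edges):
        nbrs[e.i].append((e.j, e_idx))
        nbrs[e.j].append((e.i, e_idx))
    for v in nbrs:
        nbrs[v].sort()
    edge_len = [e.distance for e in g.edges]

    out: dict[tuple[int, int], list[int]] = {}
    for src in range(1, n):
        depth = {src: 0}
        order = [src]
        q = deque([src])
        while q:
            u = q.popleft()
            if depth[u] == P_max:
                continue
            for v, _ in nbrs[u]:
                if v not in depth:
                    depth[v] = depth[u] + 1
                    order.append(v)
                    q.append(v)
        # among predecessors one BFS level up, pick the geometrically
        # shortest continuation (index as the final tie-break)
        best_len: dict[int, float] = {src: 0.0}
        parent: dict[int, tuple[int, int]] = {}
        for v in order[1:]:
            cands = [
                (best_len[u] + edge_len[e_idx], u, e_idx)
                for u, e_idx in nbrs[v]
                if u in best_len and depth.get(u, -1) == depth[v] - 1
            ]
            total, u, e_idx = min(cands)
            best_len[v] = total
            parent[v] = (u, e_idx)
        for dst, d in depth.items():
            if dst == src:
                continue
            path = []
            v = dst
            while v != src:
                u, e_idx = parent[v]
                path.append(e_idx)
                v = u
            out[(src, dst)] = path[::-1]
    return out


def angle_sums(g: ComplexGraph) -> dict[tuple[int, int], float]:
    """Summed bond angles (degrees) per covalently bonded ordered pair (i, j).

    For each covalent edge (i, j), the entry at (i, j) is the sum over
    covalent neighbors k != i of j of the angle i-j-k at vertex j. The
    reverse orientation (j, i) sums angles at vertex i. Pairs with no third
    atom get 0.
    """
    cov_adj: dict[int, set[int]] = {}
    for e in g.edges:
        if e.kind != "covalent":
            continue
        cov_adj.setdefault(e.i, set()).add(e.j)
        cov_adj.setdefault(e.j, set()).add(e.i)

    out: dict[tuple[int, int], float] = {}
    for j, neigh in cov_adj.items():
        for i in neigh:
            total = 0.0
            v_ji = g.coords[i] - g.coords[j]
            n_ji = np.linalg.norm(v_ji)
            if n_ji == 0:
                raise ArithmeticError(f"zero-length bond vector between nodes {i} and {j}")
            for k in neigh:
                if k == i:
                    continue
                v_jk = g.coords[k] - g.coords[j]
                n_jk = np.linalg.norm(v_jk)
                if n_jk == 0:
                    raise ArithmeticError(f"zero-length bond vector between nodes {j} and {k}")
                cosang = np.clip(np.dot(v_ji, v_jk) / (n_ji * n_jk), -1.0, 1.0)
                total += float(np.degrees(np.arccos(cosang)))
            out[(i, j)] = total
    return out


# ---------------------------------------------------------------------------
# JSON serialization


def graph_to_json(g: ComplexGraph) -> dict:
    return {
        "format_version": 1,
        "nodes": [list(n.as_codes()) + [int(n.is_virtual)] for n in g.nodes],
        "coords": [[None if np.isnan(v) else float(v) for v in row] for row in g.coords],
        "edges": [
            [e.i, e.j, e.kind, e.bond_order, e.conjugated, e.in_ring, e.distance]
            for e in g.edges
        ],
        "sp_paths": {f"{i},{j}": p for (i, j), p in g.sp_paths.items()},
        "angle_sum": {f"{i},{j}": v for (i, j), v in g.angle_sum.items()},
        "label_pKi": g.label_pKi,
        "atom_index": g.atom_index,
    }


def graph_from_json(obj: dict) -> ComplexGraph:
    nodes = []
    for row in obj["nodes"]:
        nodes.append(NodeFeatures(
            element=row[0], degree=row[1], formal_charge=row[2],
            hydrogen_count=row[3], hybridization=row[4], is_aromatic=row[5],
            in_ring=row[6], chirality=row[7], origin=row[8], is_virtual=bool(row[9]),
        ))
    coords = np.array(
        [[np.nan if v is None else v for v in row] for row in obj["coords"]], dtype=float
    )
    edges = [
        EdgeRecord(i=r[0], j=r[1], kind=r[2], bond_order=r[3],
                   conjugated=r[4], in_ring=r[5], distance=r[6])
        for r in obj["edges"]
    ]
    sp = {tuple(map(int, k.split(","))): v for k, v in obj["sp_paths"].items()}
    ang = {tuple(map(int, k.split(","))): v for k, v in obj["angle_sum"].items()}
    return ComplexGraph(nodes=nodes, coords=coords, edges=edges, sp_paths=sp,
                        angle_sum=ang, label_pKi=obj.get("label_pKi"),
                        atom_index=obj.get("atom_index"))
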