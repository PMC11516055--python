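"""Graph construction: pocket cutoffs, edges, shortest paths, angle sums."""

from __future__ import annotations

import numpy as np
import pytest

from dynabind.featurize import (
    ComplexGraph, FeaturizerConfig, angle_sums, build_graph, graph_from_json,
    graph_to_json, select_pocket, shortest_paths,
)
from dynabind.structures import AtomRecord, ComplexStructure
from dynabind.synthgen import SynthConfig, make_complex

from conftest import permuted, random_rigid_transform, transformed


def simple_complex(prot_positions, lig_positions=((0.0, 0.0, 0.0),),
                   lig_bonds=()):
    atoms = []
    for pos in lig_positions:
        atoms.append(AtomRecord(index=len(atoms), element="C",
                                coords=np.array(pos), origin="ligand"))
    for pos in prot_positions:
        atoms.append(AtomRecord(index=len(atoms), element="C",
                                coords=np.array(pos), origin="protein",
                                residue_id=f"A:GLY:{len(atoms)}"))
    return ComplexStructure(atoms=atoms, ligand_bonds=set(lig_bonds))


class TestPocketSelection:
    def test_inclusive_cutoff_boundary(self):
        cplx = simple_complex([(4.9, 0, 0), (5.0, 0, 0), (5.1, 0, 0)])
        pocket = select_pocket(cplx, FeaturizerConfig(d_p=5.0))
        dists = sorted(np.linalg.norm(cplx.atoms[i].coords) for i in pocket)
        assert dists == pytest.approx([4.9, 5.0])

    def test_exclusive_cutoff_drops_boundary(self):
        cplx = simple_complex([(4.9, 0, 0), (5.0, 0, 0)])
        pocket = select_pocket(cplx, FeaturizerConfig(d_p=5.0, cutoff_inclusive=False))
        assert len(pocket) == 1

    def test_empty_pocket_warns(self):
        cplx = simple_complex([(4.9, 0, 0)])
        with pytest.warns(UserWarning):
            pocket = select_pocket(cplx, FeaturizerConfig(d_p=0.5))
        assert pocket == set()

    def test_everything_close_keeps_all(self):
        cplx = simple_complex([(0.9, 0, 0), (0, 0.8, 0), (0, 0, 0.7)])
        pocket = select_pocket(cplx, FeaturizerConfig(d_p=5.0))
        assert pocket == set(cplx.protein_indices)


class TestBuildGraph:
    def test_minimal_graph_counts(self):
        # two bonded ligand atoms 1.5 A apart, one pocket atom 3 A from each
        cplx = simple_complex(
            prot_positions=[(0.75, np.sqrt(9 - 0.75 ** 2), 0)],
            lig_positions=[(0, 0, 0), (1.5, 0, 0)],
            lig_bonds={(0, 1, 1)},
        )
        g = build_graph(cplx, FeaturizerConfig())
        assert g.n_nodes == 4  # virtual + 2 ligand + 1 pocket
        kinds = sorted(e.kind for e in g.edges)
        assert kinds == ["covalent", "noncovalent", "noncovalent"]

    def test_tight_ds_leaves_only_covalent(self):
        cplx = simple_complex(
            prot_positions=[(0.75, 3.0, 0)],
            lig_positions=[(0, 0, 0), (1.5, 0, 0)],
            lig_bonds={(0, 1, 1)},
        )
        g = build_graph(cplx, FeaturizerConfig(d_s=0.5))
        assert [e.kind for e in g.edges] == ["covalent"]

    def test_rigid_invariance_of_all_fields(self):
        cplx = make_complex(SynthConfig(seed=3))
        rng = np.random.default_rng(5)
        g0 = build_graph(cplx)
        g1 = build_graph(transformed(cplx, random_rigid_transform(rng)))
        assert [n.as_codes() for n in g0.nodes] == [n.as_codes() for n in g1.nodes]
        assert [(e.i, e.j, e.kind) for e in g0.edges] == [(e.i, e.j, e.kind) for e in g1.edges]
        np.testing.assert_allclose([e.distance for e in g0.edges],
                                   [e.distance for e in g1.edges], atol=1e-9)
        assert g0.sp_paths == g1.sp_paths
        for key in g0.angle_sum:
            assert g0.angle_sum[key] == pytest.approx(g1.angle_sum[key], abs=1e-8)

    def test_permutation_equivariance(self):
        cplx = make_complex(SynthConfig(seed=4))
        rng = np.random.default_rng(9)
        perm = rng.permutation(cplx.n_atoms)
        g0 = build_graph(cplx)
        g1 = build_graph(permuted(cplx, perm))
        # node multisets and pairwise quantity multisets must agree
        assert sorted(n.as_codes() for n in g0.nodes) == sorted(n.as_codes() for n in g1.nodes)
        assert sorted(round(e.distance, 6) for e in g0.edges) == \
               sorted(round(e.distance, 6) for e in g1.edges)
        assert sorted(round(v, 6) for v in g0.angle_sum.values()) == \
               sorted(round(v, 6) for v in g1.angle_sum.values())

    def test_edge_sets_match_bruteforce(self):
        """Edges equal an O(n^2) enumeration under the cutoffs (100 seeds)."""
        cfg = FeaturizerConfig(d_p=5.0, d_s=5.0)
        for seed in range(100):
            cplx = make_complex(SynthConfig(
                seed=seed, n_ligand_atoms=3 + seed % 6, n_pocket_atoms=2 + seed % 7))
            g = build_graph(cplx, cfg)
            idx = g.atom_index
            xyz = cplx.coords
            kept = set(idx[1:])
            cov = {tuple(sorted((i, j))) for i, j, _ in cplx.ligand_bonds
                   if i in kept and j in kept}
            expect_noncov = set()
            kept_sorted = sorted(kept)
            for a_pos, i in enumerate(kept_sorted):
                for j in kept_sorted[a_pos + 1:]:
                    pair = (i, j)
                    if pair in cov:
                        continue
                    if np.linalg.norm(xyz[i] - xyz[j]) <= cfg.d_s:
                        expect_noncov.add(pair)
            got_cov = {tuple(sorted((idx[e.i], idx[e.j]))) for e in g.edges
                       if e.kind == "covalent"}
            got_noncov = {tuple(sorted((idx[e.i], idx[e.j]))) for e in g.edges
                          if e.kind == "noncovalent"}
            assert got_cov == cov, f"seed {seed}"
            assert got_noncov == expect_noncov, f"seed {seed}"

    def test_graph_json_roundtrip(self, toy_graph):
        g2 = graph_from_json(graph_to_json(toy_graph))
        assert [n.as_codes() for n in g2.nodes] == [n.as_codes() for n in toy_graph.nodes]
        assert g2.sp_paths == toy_graph.sp_paths
        assert len(g2.edges) == len(toy_graph.edges)


def path_graph(n_nodes, edges):
    """Build a bare ComplexGraph carrying only connectivity for pathfinding."""
    from dynabind.featurize import EdgeRecord, _VIRTUAL_NODE

    recs = [EdgeRecord(i=i, j=j, kind="covalent", bond_order=1, conjugated=1,
                       in_ring=1, distance=1.5) for i, j in edges]
    return ComplexGraph(nodes=[_VIRTUAL_NODE] * (n_nodes + 1),
                        coords=np.zeros((n_nodes + 1, 3)),
                        edges=recs, sp_paths={}, angle_sum={})


class TestShortestPaths:
    def test_path_graph_two_hops(self):
        g = path_graph(3, [(1, 2), (2, 3)])
        sp = shortest_paths(g, P_max=5)
        assert sp[(1, 3)] == [0, 1]
        assert sp[(3, 1)] == [1, 0]

    def test_disconnected_pair_absent(self):
        g = path_graph(4, [(1, 2), (3, 4)])
        sp = shortest_paths(g, P_max=5)
        assert (1, 3) not in sp and (2, 4) not in sp

    def test_four_cycle_lowest_index_tiebreak(self):
        # cycle 1-2-3-4-1: sp(1,3) must run through node 2, not node 4
        g = path_graph(4, [(1, 2), (2, 3), (3, 4), (1, 4)])
        sp = shortest_paths(g, P_max=5)
        assert len(sp[(1, 3)]) == 2
        assert sp[(1, 3)] == [0, 1]  # edges (1,2), (2,3)

    def test_pmax_caps_entries(self):
        g = path_graph(5, [(1, 2), (2, 3), (3, 4), (4, 5)])
        sp = shortest_paths(g, P_max=2)
        assert (1, 3) in sp and (1, 4) not in sp

    def test_lengths_match_bfs_oracle(self):
        """Path lengths equal an independent all-pairs BFS on random graphs."""
        import networkx as nx

        rng = np.random.default_rng(17)
        for trial in range(100):
            n = int(rng.integers(4, 12))
            possible = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
            chosen = [possible[k] for k in
                      rng.choice(len(possible), size=min(len(possible), n + 2), replace=False)]
            g = path_graph(n, chosen)
            sp = shortest_paths(g, P_max=10)
            nxg = nx.Graph(chosen)
            nxg.add_nodes_from(range(1, n + 1))
            truth = dict(nx.all_pairs_shortest_path_length(nxg))
            for i in range(1, n + 1):
                for j in range(1, n + 1):
                    if i == j:
                        continue
                    d = truth.get(i, {}).get(j)
                    if d is None or d > 10:
                        assert (i, j) not in sp
                    else:
                        assert len(sp[(i, j)]) == d, f"trial {trial} pair {(i, j)}"


class TestAngleSums:
    def _chain(self, positions, bonds):
        atoms = [AtomRecord(index=k, element="C", coords=np.array(p), origin="ligand")
                 for k, p in enumerate(positions)]
        cplx = ComplexStructure(atoms=atoms,
                                ligand_bonds={(min(i, j), max(i, j), 1) for i, j in bonds})
        return build_graph(cplx, FeaturizerConfig(d_s=0.01))

    def test_right_angle(self):
        # i at x, j at origin, k at y: angle at j is 90 degrees
        g = self._chain([(1.5, 0, 0), (0, 0, 0), (0, 1.5, 0)], [(0, 1), (1, 2)])
        # ligand atom 0 -> node 1, atom 1 -> node 2, atom 2 -> node 3
        assert g.angle_sum[(1, 2)] == pytest.approx(90.0, abs=1e-9)
        assert g.angle_sum[(3, 2)] == pytest.approx(90.0, abs=1e-9)

    def test_terminal_bond_zero(self):
        g = self._chain([(1.5, 0, 0), (0, 0, 0)], [(0, 1)])
        assert g.angle_sum[(2, 1)] == 0.0  # vertex is terminal: empty sum

    def test_linear_plus_perpendicular_sums(self):
        # i-j-k collinear (180) plus k' perpendicular (90): sum = 270 at vertex j
        g = self._chain(
            [(1.5, 0, 0), (0, 0, 0), (-1.5, 0, 0), (0, 1.5, 0)],
            [(0, 1), (1, 2), (1, 3)],
        )
        assert g.angle_sum[(1, 2)] == pytest.approx(270.0, abs=1e-9)

    def test_symmetry_of_bonded_pairs(self, toy_graph):
        for (i, j) in toy_graph.angle_sum:
            assert (j, i) in toy_graph.angle_sum

    def test_matches_bruteforce_oracle(self):
        """Angle sums equal an O(n^3) triple loop on random structures."""
        for seed in range(30):
            cplx = make_complex(SynthConfig(seed=seed, n_ligand_atoms=3 + seed % 8,
                                            n_pocket_atoms=3))
            g = build_graph(cplx)
            idx = g.atom_index
            xyz = {n: cplx.coords[idx[n]] for n in range(1, g.n_nodes)}
            cov = {}
            for e in g.edges:
                if e.kind == "covalent":
                    cov.setdefault(e.i, set()).add(e.j)
                    cov.setdefault(e.j, set()).add(e.i)
            for j, neigh in cov.items():
                for i in neigh:
                    expect = 0.0
                    for k in neigh:
                        if k == i:
                            continue
                        u = xyz[i] - xyz[j]
                        v = xyz[k] - xyz[j]
                        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                        expect += np.degrees(np.arccos(np.clip(c, -1, 1)))
                    assert g.angle_sum[(i, j)] == pytest.approx(expect, abs=1e-9)

    def test_zero_length_bond_rejected(self):
        atoms = [AtomRecord(index=0, element="C", coords=np.zeros(3), origin="ligand"),
                 AtomRecord(index=1, element="C", coords=np.zeros(3), origin="ligand"),
                 AtomRecord(index=2, element="C", coords=np.array([1.5, 0, 0]),
                            origin="ligand")]
        cplx = ComplexStructure(atoms=atoms, ligand_bonds={(0, 1, 1), (1, 2, 1)})
        with pytest.raises(ArithmeticError):
            build_graph(cplx, FeaturizerConfig(d_s=0.01))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"d_p": 0.0}, {"d_s": -1.0}, {"P_max": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FeaturizerConfig(**kwargs)
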