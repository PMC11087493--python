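import itertools

import networkx as nx
import numpy as np
import pytest

from capsipy import fixtures
from capsipy.energetics import (
    VDW_PARAMS,
    EnergyParams,
    InterfaceEnergy,
    build_assembly_graph,
    classify_all_interfaces,
    connectivity_cutoff,
    enumerate_interfaces,
    greedy_assemble,
    n_distinct_energy_levels,
    score_interface,
    shrake_rupley_sasa,
)
from capsipy.structure_io import Atom, Chain, Residue, Structure, icosahedron_vertices


def atom_chain(chain_id, atoms, res_name="ALA", role="unassigned"):
    """Chain with one residue holding the given (name, element, xyz) atoms."""
    res = Residue(chain_id, 1, res_name, [
        Atom(i + 1, name, el, np.asarray(xyz, dtype=float))
        for i, (name, el, xyz) in enumerate(atoms)
    ])
    return Chain(chain_id, [res], protomer_role=role)


class TestSasa:
    def test_isolated_atom_full_sphere(self):
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), ["C"])
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert sasa[0] == pytest.approx(expected, rel=1e-12)

    def test_fully_buried_atom(self):
        # central atom caged by 12 close neighbors loses all its surface
        verts = icosahedron_vertices() * 2.0
        coords = np.vstack([np.zeros(3), verts])
        sasa = shrake_rupley_sasa(coords, ["C"] * 13)
        assert sasa[0] == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, size=(20, 3))
        a = shrake_rupley_sasa(coords, ["C"] * 20)
        b = shrake_rupley_sasa(coords, ["C"] * 20)
        np.testing.assert_array_equal(a, b)


class TestScoreInterface:
    def test_non_interacting_limit(self):
        a = atom_chain("A", [("CB", "C", (0, 0, 0))])
        b = atom_chain("B", [("CB", "C", (100, 0, 0))])
        e = score_interface(a, b)
        assert e.e_vdw == 0.0
        assert e.e_es == 0.0
        assert e.e_ds == pytest.approx(0.0, abs=1e-9)

    def test_vdw_minimum_exact(self):
        """Two like atoms at the 12-6 minimum separation score exactly -eps."""
        rmin2, eps = VDW_PARAMS["C"]
        a = atom_chain("A", [("CB", "C", (0, 0, 0))])
        b = atom_chain("B", [("CB", "C", (2 * rmin2, 0, 0))])
        e = score_interface(a, b)
        assert e.e_vdw == pytest.approx(-eps, rel=1e-12)

    def test_coulomb_term_hand_oracle(self):
        """Two unit charges at 10 Å, eps=10: k·q²/(ε·r) evaluated by hand."""
        a = atom_chain("A", [("NZ", "N", (0, 0, 0))], res_name="LYS")
        b = atom_chain("B", [("NZ", "N", (10, 0, 0))], res_name="LYS")
        params = EnergyParams(vdw_cutoff=0.001)  # isolate the Coulomb term
        e = score_interface(a, b, params)
        expected = 332.0636 * (1.0 * 1.0) / (10.0 * 10.0)
        assert e.e_es == pytest.approx(expected, rel=1e-12)
        assert e.e_es > 0  # like charges repel

    def test_opposite_charges_attract(self):
        lys = atom_chain("A", [("NZ", "N", (0, 0, 0))], res_name="LYS")
        asp = atom_chain("B", [("OD1", "O", (6, 0, 0)), ("OD2", "O", (7, 0, 0))],
                         res_name="ASP")
        e = score_interface(lys, asp, EnergyParams(vdw_cutoff=0.001))
        assert e.e_es < 0

    def test_total_is_exact_sum(self):
        a = atom_chain("A", [("CB", "C", (0, 0, 0)), ("NZ", "N", (1.5, 0, 0))],
                       res_name="LYS")
        b = atom_chain("B", [("CB", "C", (4, 0, 0)), ("OD1", "O", (5, 1, 0))],
                       res_name="ASP")
        e = score_interface(a, b)
        assert e.e_total == e.e_vdw + e.e_es + e.e_ds

    def test_symmetric_in_chain_order(self):
        a = atom_chain("A", [("CB", "C", (0, 0, 0)), ("NZ", "N", (1.5, 0, 0))],
                       res_name="LYS")
        b = atom_chain("B", [("CB", "C", (4, 0, 0)), ("OD1", "O", (5, 1, 0))],
                       res_name="ASP")
        e1, e2 = score_interface(a, b), score_interface(b, a)
        assert e1.e_vdw == pytest.approx(e2.e_vdw, rel=1e-12)
        assert e1.e_es == pytest.approx(e2.e_es, rel=1e-12)
        assert e1.e_ds == pytest.approx(e2.e_ds, rel=1e-12)

    def test_rigid_body_invariance(self):
        a = atom_chain("A", [("CB", "C", (0, 0, 0)), ("NZ", "N", (1.5, 0, 0))],
                       res_name="LYS")
        b = atom_chain("B", [("CB", "C", (4, 0, 0)), ("OD1", "O", (5, 1, 0))],
                       res_name="ASP")
        s = Structure("pair", [a, b])
        rng = np.random.default_rng(0)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = s.transform(q, np.array([5.0, -3.0, 8.0]))
        e0 = score_interface(s.chains[0], s.chains[1])
        e1 = score_interface(moved.chains[0], moved.chains[1])
        assert e1.e_vdw == pytest.approx(e0.e_vdw, rel=1e-9)
        assert e1.e_es == pytest.approx(e0.e_es, rel=1e-9)
        # SASA sampling lattice is not rotated with the atoms: small tolerance
        assert e1.e_ds == pytest.approx(e0.e_ds, abs=0.05)

    def test_unknown_element_rejected(self):
        a = atom_chain("A", [("FE", "FE", (0, 0, 0))])
        b = atom_chain("B", [("CB", "C", (3, 0, 0))])
        with pytest.raises(KeyError, match="FE"):
            score_interface(a, b)


class TestInterfaceEnumeration:
    def test_vertex_capsid_single_class_five_neighbors(self, vertex_capsid):
        edge = 20.0 * np.linalg.norm(
            icosahedron_vertices()[0] - icosahedron_vertices()[1])
        # impossible to bridge non-adjacent vertices at this cutoff
        descs = enumerate_interfaces(vertex_capsid, contact_cutoff=edge + 0.5)
        assert len(descs) == 1
        _, edge_class = classify_all_interfaces(vertex_capsid, edge + 0.5)
        degree = {}
        for ca, cb in edge_class:
            degree[ca] = degree.get(ca, 0) + 1
            degree[cb] = degree.get(cb, 0) + 1
        assert set(degree.values()) == {5}

    def test_isolated_chains_no_interfaces(self):
        a = atom_chain("A", [("CB", "C", (0, 0, 0))])
        b = atom_chain("B", [("CB", "C", (50, 0, 0))])
        s = Structure("iso", [a, b])
        assert enumerate_interfaces(s, contact_cutoff=5.0) == []

    def test_missing_reference_rejected(self, vertex_capsid):
        with pytest.raises(KeyError):
            enumerate_interfaces(vertex_capsid, reference_chain="Z")

    def test_dimer_capsid_interface_classes(self):
        """A 2-chain (role A/B) unit expanded to 120 protomers: the reference
        protomer's neighbors merge into a small set of unique classes that
        includes the intra-dimer interface."""
        mono = fixtures.make_random_structure(5, box_size=12.0, seed=2,
                                              chain_ids=("A", "B"))
        mono.chain("A").protomer_role = "A"
        mono.chain("B").protomer_role = "B"
        cap = fixtures.make_toy_capsid(mono, radius=40.0)
        assert len(cap.chains) == 120
        descs = enumerate_interfaces(cap, reference_chain="A_op00",
                                     contact_cutoff=14.0)
        assert len(descs) >= 1
        roles = {tuple(sorted(d.partner_roles)) for d in descs}
        assert ("A", "B") in roles  # the intra-dimer contact survives merging


class TestAssemblyGraph:
    def test_vertex_capsid_icosahedron_graph(self, vertex_capsid):
        edge = 20.0 * np.linalg.norm(
            icosahedron_vertices()[0] - icosahedron_vertices()[1])
        g = build_assembly_graph(
            vertex_capsid, {0: InterfaceEnergy(0, -2.0, 0.0, 0.0)},
            contact_cutoff=edge + 0.5)
        assert g.number_of_nodes() == 12
        assert g.number_of_edges() == 30  # icosahedron edge count
        assert nx.is_connected(g)

    def test_missing_class_energy_rejected(self, vertex_capsid):
        edge = 20.0 * np.linalg.norm(
            icosahedron_vertices()[0] - icosahedron_vertices()[1])
        with pytest.raises(KeyError, match="interface classes"):
            build_assembly_graph(vertex_capsid, {}, contact_cutoff=edge + 0.5)


class TestGreedyAssembly:
    def test_path_graph_forced_order(self):
        g = nx.Graph()
        g.add_edge("a", "b", e_total=-5.0)
        g.add_edge("b", "c", e_total=-1.0)
        steps = greedy_assemble(g, start_node="a")
        assert [s.placed_node for s in steps] == ["b", "c"]
        assert [s.delta_e for s in steps] == [-5.0, -1.0]
        assert steps[-1].cumulative_e == -6.0

    def test_triangle_tiebreak_and_additivity(self):
        g = nx.Graph()
        for u, v in [("n0", "n1"), ("n1", "n2"), ("n0", "n2")]:
            g.add_edge(u, v, e_total=-2.0)
        steps = greedy_assemble(g, start_node="n0")
        assert steps[0].placed_node == "n1"  # tie broken by lowest id
        assert steps[1].delta_e == -4.0  # closes two edges at once

    def test_disconnected_graph_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", e_total=-1.0)
        g.add_node("z")
        with pytest.raises(ValueError, match="z"):
            greedy_assemble(g, start_node="a")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_argmin_oracle(self, seed):
        """Random connected graphs ≤ 12 nodes: trajectory equals a naive
        per-step recomputation of every candidate's docking energy."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = nx.Graph()
        nodes = [f"m{i:02d}" for i in range(n)]
        # random spanning tree + extra edges guarantees connectivity
        for i in range(1, n):
            j = int(rng.integers(i))
            g.add_edge(nodes[i], nodes[j],
                       e_total=float(np.round(rng.uniform(-10, -0.5), 3)))
        for _ in range(n):
            i, j = rng.integers(n, size=2)
            if i != j and not g.has_edge(nodes[i], nodes[j]):
                g.add_edge(nodes[i], nodes[j],
                           e_total=float(np.round(rng.uniform(-10, -0.5), 3)))

        start = nodes[0]
        steps = greedy_assemble(g, start_node=start)

        # oracle: recompute each step's full candidate set from scratch
        placed = {start}
        for step in steps:
            candidates = {}
            for node in g.nodes:
                if node in placed:
                    continue
                edges = [g.edges[node, p]["e_total"]
                         for p in g.neighbors(node) if p in placed]
                if edges:
                    candidates[node] = sum(edges)
            best = min(candidates, key=lambda m: (candidates[m], m))
            assert step.placed_node == best
            assert step.delta_e == pytest.approx(candidates[best], abs=1e-9)
            placed.add(best)

    def test_cumulative_equals_internal_edge_sum(self):
        """Incremental bookkeeping equals recomputation over placed edges."""
        rng = np.random.default_rng(99)
        g = nx.gnm_random_graph(15, 40, seed=3)
        for u, v in g.edges:
            g.edges[u, v]["e_total"] = float(rng.uniform(-5, -1))
        assert nx.is_connected(g)
        steps = greedy_assemble(g, start_node=0)
        placed = {0}
        for step in steps:
            placed.add(step.placed_node)
            internal = sum(
                g.edges[u, v]["e_total"]
                for u, v in g.edges
                if u in placed and v in placed
            )
            assert step.cumulative_e == pytest.approx(internal, abs=1e-9)

    def test_120_node_toy_capsid_trajectory(self):
        """Full T=1-sized toy capsid: 119 additions, energy conservation."""
        mono = fixtures.make_random_structure(3, box_size=8.0, seed=4,
                                              chain_ids=("A", "B"))
        mono.chain("A").protomer_role = "A"
        mono.chain("B").protomer_role = "B"
        cap = fixtures.make_toy_capsid(mono, radius=35.0)
        cutoff = connectivity_cutoff(cap)
        classes, edge_class = classify_all_interfaces(cap, contact_cutoff=cutoff)
        energies = {
            d.interface_id: InterfaceEnergy(
                d.interface_id, -1.0 - 0.5 * d.interface_id, 0.0, 0.0)
            for d in classes
        }
        g = build_assembly_graph(cap, energies, contact_cutoff=cutoff)
        assert g.number_of_nodes() == 120
        assert nx.is_connected(g)
        steps = greedy_assemble(g)
        assert len(steps) == 119
        edge_sum = sum(d["e_total"] for _, _, d in g.edges(data=True))
        assert steps[-1].cumulative_e == pytest.approx(edge_sum, abs=1e-6)
        assert n_distinct_energy_levels(steps) >= 1


class TestParams:
    def test_minimum_sampling_density_enforced(self):
        with pytest.raises(ValueError, match="960"):
            EnergyParams(n_sphere_points=100)
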