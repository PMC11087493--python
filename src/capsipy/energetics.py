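"""Capsomere interface enumeration, energy scoring, and greedy assembly.

The interface energy decomposes additively into three terms,

    E_total = E_vdw + E_es + E_ds,

a truncated 12-6 van der Waals sum, a constant-dielectric Coulomb sum over
formal side-chain charges, and an atomic-solvation desolvation term driven
by the surface area buried on complex formation.  This is an internal,
fully documented rigid-body scoring backend: absolute values are in
kcal/mol-like units but only signs, rankings, and the exact decomposition
are meaningful for downstream use.

The assembly simulator follows the energetics greedily: starting from one
protomer it repeatedly docks the unplaced neighbor with the most favorable
summed interface energy to the growing shell until the capsid is complete.
A static greedy pathway of this kind says nothing about assembly kinetics
in vivo; it orders subunits by template energetics only.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Chain, Structure, strip_operator_suffix

__all__ = [
    "EnergyParams",
    "InterfaceDescriptor",
    "InterfaceEnergy",
    "AssemblyStep",
    "shrake_rupley_sasa",
    "score_interface",
    "enumerate_interfaces",
    "build_assembly_graph",
    "greedy_assemble",
    "assembly_records",
]

# Lennard-Jones per-element parameters: (rmin/2 in Å, epsilon in kcal/mol).
# Combining rules: rmin_ij = rmin2_i + rmin2_j, eps_ij = sqrt(eps_i * eps_j).
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "C": (1.90, 0.086),
    "N": (1.85, 0.170),
    "O": (1.70, 0.120),
    "S": (2.00, 0.450),
    "P": (2.10, 0.585),
    "H": (1.00, 0.030),
}

# Formal-charge-based partial charges per (residue, atom) at neutral pH;
# charge is split over the equivalent terminal atoms of each group.
PARTIAL_CHARGES: dict[tuple[str, str], float] = {
    ("ARG", "NH1"): +0.5,
    ("ARG", "NH2"): +0.5,
    ("LYS", "NZ"): +1.0,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
}

# Atomic solvation parameters, kcal/(mol·Å²): burying apolar surface is
# favorable (negative), burying polar surface costs energy (positive).
ASP_PARAMS: dict[str, float] = {
    "C": -0.0151,
    "S": -0.0110,
    "N": +0.0228,
    "O": +0.0228,
    "P": +0.0228,
    "H": 0.0,
}

# van der Waals radii (Å) for surface-area sampling.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}


@dataclasses.dataclass
class EnergyParams:
    """Tunable knobs of the rigid-body interface score."""

    vdw_cutoff: float = 8.5  # Å, pair-potential truncation
    dielectric: float = 10.0  # constant screening for the Coulomb sum
    coulomb_constant: float = 332.0636  # kcal·Å/(mol·e²)
    probe_radius: float = 1.4  # Å, solvent probe for SASA
    n_sphere_points: int = 960  # deterministic points per atom (≥ 960)

    def __post_init__(self) -> None:
        if self.n_sphere_points < 960:
            raise ValueError("SASA sampling requires at least 960 points per atom")


@dataclasses.dataclass
class InterfaceDescriptor:
    interface_id: int
    partner_chains: tuple[str, str]
    partner_roles: tuple[str, str]
    operator_pair: tuple[int | None, int | None]
    contact_residues_a: tuple
    contact_residues_b: tuple
    n_atom_contacts: int
    fingerprint: tuple = ()


@dataclasses.dataclass
class InterfaceEnergy:
    interface_id: int
    e_vdw: float
    e_es: float
    e_ds: float

    @property
    def e_total(self) -> float:
        return self.e_vdw + self.e_es + self.e_ds


@dataclasses.dataclass
class AssemblyStep:
    step_index: int  # 1-based
    placed_node: str
    delta_e: float
    cumulative_e: float


# ---------------------------------------------------------------------------
# surface area


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: Sequence[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley style.

    Each atom's expanded sphere (vdW + probe radius) is sampled with a
    deterministic golden-spiral point lattice; points falling inside any
    neighbor's expanded sphere are occluded.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII.get(e, 1.70) for e in elements]) + probe_radius
    n = len(coords)
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    sasa = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = n_points
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * accessible / n_points
    return sasa


# ---------------------------------------------------------------------------
# energy components


def _chain_arrays(chain: Chain) -> tuple[np.ndarray, list[str], np.ndarray]:
    """(coords, elements, charges) for a chain's atoms."""
    coords, elements, charges = [], [], []
    for res in chain.residues:
        for atom in res.atoms:
            coords.append(atom.position)
            elements.append(atom.element.upper())
            charges.append(PARTIAL_CHARGES.get((res.res_name, atom.name), 0.0))
    return np.array(coords), elements, np.array(charges)


def _vdw_pair_params(elements: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    rmin2, eps = [], []
    for e in elements:
        if e not in VDW_PARAMS:
            raise KeyError(f"no van der Waals parameters for element {e!r}")
        r, ep = VDW_PARAMS[e]
        rmin2.append(r)
        eps.append(ep)
    return np.array(rmin2), np.array(eps)


def score_interface(
    side_a: Chain, side_b: Chain, params: EnergyParams | None = None,
    interface_id: int = -1,
) -> InterfaceEnergy:
    """Decomposed rigid-body interaction energy of two chains.

    E_vdw: 12-6 potential over inter-chain heavy-atom pairs within the
    cutoff (Lorentz–Berthelot combining of the bundled per-element table).
    E_es: Coulomb sum over formal side-chain charges with constant
    dielectric.  E_ds: atomic-solvation-parameter-weighted surface area
    buried on complex formation.  The total is the exact sum of the three.
    """
    params = params or EnergyParams()
    xa, ea, qa = _chain_arrays(side_a)
    xb, eb, qb = _chain_arrays(side_b)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("both chains must have atoms with coordinates")

    ra, epsa = _vdw_pair_params(ea)
    rb, epsb = _vdw_pair_params(eb)

    # pairwise distances, restricted to the cutoff
    d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2))
    within = (d > 0) & (d <= params.vdw_cutoff)
    e_vdw = 0.0
    if within.any():
        ia, ib = np.nonzero(within)
        rmin = ra[ia] + rb[ib]
        eps = np.sqrt(epsa[ia] * epsb[ib])
        ratio = rmin / d[ia, ib]
        e_vdw = float(np.sum(eps * (ratio**12 - 2.0 * ratio**6)))

    # Coulomb over charged atoms only (no cutoff; 1/r decays smoothly)
    e_es = 0.0
    ca, cb = np.nonzero(qa)[0], np.nonzero(qb)[0]
    if len(ca) and len(cb):
        dq = np.sqrt(((xa[ca][:, None, :] - xb[cb][None, :, :]) ** 2).sum(axis=2))
        with np.errstate(divide="ignore"):
            e_es = float(
                params.coulomb_constant
                * np.sum(np.outer(qa[ca], qb[cb]) / (params.dielectric * dq))
            )

    # desolvation: buried SASA weighted by atomic solvation parameters
    sasa_a = shrake_rupley_sasa(xa, ea, params.probe_radius, params.n_sphere_points)
    sasa_b = shrake_rupley_sasa(xb, eb, params.probe_radius, params.n_sphere_points)
    sasa_ab = shrake_rupley_sasa(
        np.vstack([xa, xb]), ea + eb, params.probe_radius, params.n_sphere_points
    )
    delta_sasa = np.concatenate([sasa_a, sasa_b]) - sasa_ab  # ≥ 0 up to sampling
    asp = np.array([ASP_PARAMS.get(e, 0.0) for e in ea + eb])
    e_ds = float(np.sum(asp * delta_sasa))

    return InterfaceEnergy(interface_id, e_vdw, e_es, e_ds)


# ---------------------------------------------------------------------------
# interface enumeration


def _contacting_chain_pairs(
    expanded: Structure, cutoff: float
) -> dict[tuple[str, str], list[tuple]]:
    """Chain pairs with ≥1 inter-atomic distance ≤ cutoff.

    Returns {(chain_i, chain_j): [(res_key_i, res_key_j), ...]} with one
    entry per contacting atom pair (so the length is the atom-contact
    count), found through a single global k-d-tree pair query.
    """
    coords, chain_ids, res_keys = [], [], []
    for chain in expanded.chains:
        for res in chain.residues:
            for atom in res.atoms:
                coords.append(atom.position)
                chain_ids.append(chain.chain_id)
                res_keys.append(res.key)
    tree = cKDTree(np.array(coords))
    pairs: dict[tuple[str, str], list[tuple]] = {}
    for i, j in tree.query_pairs(cutoff):
        ci, cj = chain_ids[i], chain_ids[j]
        if ci == cj:
            continue
        if cj < ci:
            ci, cj = cj, ci
            i, j = j, i
        pairs.setdefault((ci, cj), []).append((res_keys[i], res_keys[j]))
    return pairs


def _side_identity(expanded: Structure, chain_id: str) -> str:
    """Asymmetric-unit identity of a chain copy.

    The protomer role when assigned, else the base chain id with any
    ``_opNN`` copy suffix stripped — so all symmetry copies of one
    protomer share an identity.
    """
    role = expanded.chain(chain_id).protomer_role
    if role != "unassigned":
        return role
    base, _ = strip_operator_suffix(chain_id)
    return base


def _interface_fingerprint(
    expanded: Structure, chain_a: str, chain_b: str, contacts: list[tuple]
) -> tuple:
    """Rotation-invariant class identity of a chain–chain interface.

    The sorted multiset of (role_a:resid, role_b:resid) residue contact
    pairs after mapping symmetry copies back to asymmetric-unit numbering;
    symmetric interfaces are canonicalized by taking the lexicographically
    smaller orientation.
    """
    id_a = _side_identity(expanded, chain_a)
    id_b = _side_identity(expanded, chain_b)
    fwd = tuple(sorted(
        ((id_a, ra[1], ra[2]), (id_b, rb[1], rb[2])) for ra, rb in contacts
    ))
    rev = tuple(sorted(
        ((id_b, rb[1], rb[2]), (id_a, ra[1], ra[2])) for ra, rb in contacts
    ))
    return min(fwd, rev)


def enumerate_interfaces(
    expanded: Structure,
    reference_chain: str | None = None,
    contact_cutoff: float = 5.0,
) -> list[InterfaceDescriptor]:
    """Unique interface classes around a reference protomer.

    Every neighboring chain copy within the contact cutoff of the
    reference yields a descriptor; descriptors sharing a residue-level
    contact fingerprint merge into one class.  For a T=1 capsid of
    asymmetric dimers this recovers the capsomere's distinct interfaces
    (the intra-dimer contact plus the surrounding inter-capsomere ones).
    """
    if not expanded.chains:
        raise ValueError("structure has no chains")
    if reference_chain is None:
        # default: lexicographically first chain (role A, identity operator
        # under the _opNN naming scheme)
        reference_chain = min(c.chain_id for c in expanded.chains)
    else:
        expanded.chain(reference_chain)  # raises if absent

    pairs = _contacting_chain_pairs(expanded, contact_cutoff)
    by_fingerprint: dict[tuple, InterfaceDescriptor] = {}
    for (ca, cb), contacts in sorted(pairs.items()):
        if reference_chain not in (ca, cb):
            continue
        fp = _interface_fingerprint(expanded, ca, cb, contacts)
        if fp in by_fingerprint:
            continue
        base_a, op_a = strip_operator_suffix(ca)
        base_b, op_b = strip_operator_suffix(cb)
        role_a = expanded.chain(ca).protomer_role
        role_b = expanded.chain(cb).protomer_role
        by_fingerprint[fp] = InterfaceDescriptor(
            interface_id=len(by_fingerprint),
            partner_chains=(ca, cb),
            partner_roles=(role_a, role_b),
            operator_pair=(op_a, op_b),
            contact_residues_a=tuple(sorted({ra for ra, _ in contacts})),
            contact_residues_b=tuple(sorted({rb for _, rb in contacts})),
            n_atom_contacts=len(contacts),
            fingerprint=fp,
        )
    return list(by_fingerprint.values())


def classify_all_interfaces(
    expanded: Structure, contact_cutoff: float = 5.0
) -> tuple[list[InterfaceDescriptor], dict[tuple[str, str], int]]:
    """All contacting chain pairs mapped to merged interface classes.

    Returns (class descriptors, {(chain_a, chain_b): interface_id}); used
    to put a class-level energy on every edge of the assembly graph.
    """
    pairs = _contacting_chain_pairs(expanded, contact_cutoff)
    classes: dict[tuple, InterfaceDescriptor] = {}
    edge_class: dict[tuple[str, str], int] = {}
    for (ca, cb), contacts in sorted(pairs.items()):
        fp = _interface_fingerprint(expanded, ca, cb, contacts)
        if fp not in classes:
            base_a, op_a = strip_operator_suffix(ca)
            base_b, op_b = strip_operator_suffix(cb)
            classes[fp] = InterfaceDescriptor(
                interface_id=len(classes),
                partner_chains=(ca, cb),
                partner_roles=(
                    expanded.chain(ca).protomer_role,
                    expanded.chain(cb).protomer_role,
                ),
                operator_pair=(op_a, op_b),
                contact_residues_a=tuple(sorted({ra for ra, _ in contacts})),
                contact_residues_b=tuple(sorted({rb for _, rb in contacts})),
                n_atom_contacts=len(contacts),
                fingerprint=fp,
            )
        edge_class[(ca, cb)] = classes[fp].interface_id
    return list(classes.values()), edge_class


# ---------------------------------------------------------------------------
# assembly graph and greedy trajectory


def build_assembly_graph(
    expanded: Structure,
    energies: Mapping[int, InterfaceEnergy] | None = None,
    contact_cutoff: float = 5.0,
    params: EnergyParams | None = None,
) -> nx.Graph:
    """Protomer contact graph with per-edge interface-class energies.

    Nodes are chain copies; each contacting pair carries its class's
    ``e_total``.  When ``energies`` is omitted, one representative pair
    per class is scored with :func:`score_interface` and the class energy
    is broadcast to all equivalent edges.
    """
    classes, edge_class = classify_all_interfaces(expanded, contact_cutoff)
    if energies is None:
        energies = {
            d.interface_id: score_interface(
                expanded.chain(d.partner_chains[0]),
                expanded.chain(d.partner_chains[1]),
                params,
                interface_id=d.interface_id,
            )
            for d in classes
        }
    missing = {d.interface_id for d in classes} - set(energies)
    if missing:
        raise KeyError(f"no energy provided for interface classes {sorted(missing)}")
    g = nx.Graph()
    g.add_nodes_from(c.chain_id for c in expanded.chains)
    for (ca, cb), iid in edge_class.items():
        g.add_edge(ca, cb, interface_id=iid, e_total=energies[iid].e_total)
    return g


def connectivity_cutoff(expanded: Structure, margin: float = 1.05) -> float:
    """Smallest chain-centroid contact cutoff keeping the assembly connected.

    The bottleneck edge of the minimum spanning tree over chain centroids,
    scaled by a safety margin.  Useful for toy capsids whose monomer size
    is not known a priori; atom-level contacts exist at any cutoff at or
    above the centroid separation.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree

    centroids = np.array([c.centroid() for c in expanded.chains])
    d = np.sqrt(((centroids[:, None] - centroids[None]) ** 2).sum(-1))
    mst = minimum_spanning_tree(d)
    return float(mst.toarray().max()) * margin


def greedy_assemble(
    g: nx.Graph, start_node: str | None = None
) -> list[AssemblyStep]:
    """Greedy monomer-addition trajectory over the assembly graph.

    Starting from one placed subunit, each step docks the unplaced node
    adjacent to the shell whose summed edge energy to the placed set is
    most favorable (minimum delta_e; ties broken by lowest node id), until
    every subunit is placed.  Returns |nodes|−1 steps whose cumulative
    energy equals the sum of e_total over all edges internal to the placed
    set at every step.
    """
    if g.number_of_nodes() == 0:
        return []
    if not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        start = start_node if start_node is not None else min(g.nodes)
        reachable = next(c for c in comps if start in c)
        unreachable = sorted(set(g.nodes) - reachable)
        raise ValueError(f"assembly graph is disconnected; unreachable nodes: {unreachable}")
    if start_node is None:
        start_node = min(g.nodes)
    elif start_node not in g:
        raise KeyError(f"start node {start_node!r} not in graph")

    placed = {start_node}
    # delta[n] = summed edge energy from candidate n into the placed set
    delta: dict[str, float] = {}
    for nb in g.neighbors(start_node):
        delta[nb] = g.edges[start_node, nb]["e_total"]

    steps: list[AssemblyStep] = []
    cumulative = 0.0
    for k in range(1, g.number_of_nodes()):
        best = min(delta, key=lambda n: (delta[n], n))
        d = delta.pop(best)
        placed.add(best)
        cumulative += d
        steps.append(AssemblyStep(k, best, d, cumulative))
        for nb in g.neighbors(best):
            if nb in placed:
                continue
            delta[nb] = delta.get(nb, 0.0) + g.edges[best, nb]["e_total"]
    return steps


def assembly_records(steps: Sequence[AssemblyStep]) -> list[dict]:
    return [
        {
            "step": s.step_index,
            "node": s.placed_node,
            "delta_e": s.delta_e,
            "cumulative_e": s.cumulative_e,
        }
        for s in steps
    ]


def n_distinct_energy_levels(steps: Sequence[AssemblyStep], decimals: int = 6) -> int:
    """Number of distinct delta_e values along a trajectory (rounded)."""
    return len({round(s.delta_e, decimals) for s in steps})
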