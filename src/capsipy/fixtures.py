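"""Deterministic synthetic inputs: planted cation-π pairs, toy capsids,
random structures, and particle fields.

Every generator is a pure function of its spec (numpy PCG64 generator,
explicitly seeded), so fixtures are reproducible bit-exactly and no
external structure downloads are required to exercise any module.  The
particle-field defaults emulate the observed micrograph statistics:
communities of 12 ± 4 virions of ~40 nm diameter.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .community_stats import ParticlePick
from .structure_io import (
    Atom,
    Chain,
    Residue,
    Structure,
    icosahedral_operators,
    icosahedron_vertices,
    expand_assembly,
)

__all__ = [
    "PlantedPairSpec",
    "ParticleFieldSpec",
    "make_planted_pair",
    "make_toy_capsid",
    "make_vertex_capsid",
    "make_random_structure",
    "make_particle_field",
]

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"

# Idealized planar side-chain templates in local coordinates (z = 0 for all
# ring atoms).  Six-rings are regular hexagons of radius 1.39 Å; the
# five-ring a regular pentagon of radius 1.18 Å; the indole is a planar
# fused bicyclic sketch.  Cation templates carry the charge-bearing atoms.


def _hexagon(names: list[str], radius: float = 1.39) -> dict[str, np.ndarray]:
    ang = np.linspace(0, 2 * np.pi, 7)[:6]
    return {
        n: np.array([radius * np.cos(a), radius * np.sin(a), 0.0])
        for n, a in zip(names, ang)
    }


def _pentagon(names: list[str], radius: float = 1.18) -> dict[str, np.ndarray]:
    ang = np.linspace(0, 2 * np.pi, 6)[:5]
    return {
        n: np.array([radius * np.cos(a), radius * np.sin(a), 0.0])
        for n, a in zip(names, ang)
    }


def _indole() -> dict[str, np.ndarray]:
    flat = {
        "CG": (0.00, 0.00),
        "CD1": (1.10, 0.80),
        "NE1": (2.35, 0.25),
        "CD2": (0.95, -1.32),
        "CE2": (2.30, -1.10),
        "CE3": (0.40, -2.60),
        "CZ2": (3.20, -2.10),
        "CZ3": (1.30, -3.60),
        "CH2": (2.70, -3.35),
    }
    return {n: np.array([x, y, 0.0]) for n, (x, y) in flat.items()}


SIDECHAIN_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    "PHE": _hexagon(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]),
    "TYR": {**_hexagon(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]),
            "OH": np.array([2.76, 0.0, 0.0])},
    "TRP": _indole(),
    "HIS": _pentagon(["CG", "ND1", "CE1", "NE2", "CD2"]),
    "ARG": {
        "CZ": np.array([0.0, 0.0, 0.0]),
        "NE": np.array([-1.33, 0.0, 0.0]),
        "NH1": np.array([0.66, 1.15, 0.0]),
        "NH2": np.array([0.66, -1.15, 0.0]),
    },
    "LYS": {"NZ": np.array([0.0, 0.0, 0.0]),
            "CE": np.array([-1.49, 0.0, 0.0])},
    "ALA": {"CB": np.array([0.0, 0.0, 0.0])},
    "GLY": {"CA": np.array([0.0, 0.0, 0.0])},
}

_ELEMENT_OF = {
    "N": "N", "O": "O", "S": "S",
}


def _element(atom_name: str) -> str:
    return _ELEMENT_OF.get(atom_name[0], "C")


def _make_residue(
    res_name: str,
    chain_id: str,
    seq_id: int,
    serial_start: int,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> tuple[Residue, int]:
    rot = np.eye(3) if rotation is None else rotation
    trans = np.zeros(3) if translation is None else translation
    res = Residue(chain_id, seq_id, res_name)
    serial = serial_start
    for name, local in SIDECHAIN_TEMPLATES[res_name].items():
        serial += 1
        res.atoms.append(Atom(serial, name, _element(name), rot @ local + trans))
    return res, serial


@dataclasses.dataclass
class PlantedPairSpec:
    """One aromatic ring + one cation placed at exact (distance, theta)."""

    distance: float  # Å, charge center to ring centroid
    theta: float  # degrees from the ring normal, in [0, 90]
    cation_type: str = "ARG"  # ARG | LYS | HIS
    ring_type: str = "TYR"  # PHE | TYR | TRP | HIS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not 0 <= self.theta <= 90:
            raise ValueError("theta must lie in [0, 90] degrees")


def make_planted_pair(spec: PlantedPairSpec) -> Structure:
    """Two-residue structure whose geometry realises the spec exactly.

    The aromatic ring lies in the z = 0 plane with centroid at the origin
    (normal = z); the cation charge center sits at
    distance · (sin θ, 0, cos θ).  For Trp the controlled centroid is the
    six-ring's; for His the imidazole midpoint defines the charge center.
    """
    ring_res, serial = _make_residue(spec.ring_type, "R", 1, 0)
    # center the controlled ring's centroid at the origin
    from .catpi_detect import RING_ATOMS

    label, names = RING_ATOMS[spec.ring_type][-1]  # TRP: control the 6-ring
    ring_pts = ring_res.atom_positions(names)
    shift = ring_pts.mean(axis=0)
    for a in ring_res.atoms:
        a.position = a.position - shift

    t = np.radians(spec.theta)
    target = spec.distance * np.array([np.sin(t), 0.0, np.cos(t)])
    cat_res, _ = _make_residue(spec.cation_type, "C", 1, serial)
    # charge centers: ARG CZ, LYS NZ, HIS midpoint(ND1, NE2) — all at the
    # template origin (HIS pentagon midpoint handled below)
    if spec.cation_type == "HIS":
        mid = cat_res.atom_positions(["ND1", "NE2"]).mean(axis=0)
    else:
        mid = np.zeros(3)
    for a in cat_res.atoms:
        a.position = a.position - mid + target

    return Structure(
        identifier=f"planted_{spec.ring_type}_{spec.cation_type}"
                   f"_{spec.distance:g}A_{spec.theta:g}deg",
        chains=[Chain("R", [ring_res]), Chain("C", [cat_res])],
    )


def make_toy_capsid(monomer: Structure, radius: float) -> Structure:
    """Icosahedral toy capsid: 60 symmetry copies of a monomer on a sphere.

    The monomer (1 chain → 60 chains; an A/B 2-chain unit → 120 chains) is
    translated so its centroid sits at the given radius along a generic
    (non-symmetry-axis) direction, then expanded with the 60 icosahedral
    rotations.  Deterministic: no randomness involved.
    """
    if monomer.n_atoms == 0:
        raise ValueError("monomer must have at least one atom")
    direction = np.array([1.0, 0.7, 0.4])
    direction /= np.linalg.norm(direction)
    all_xyz = np.vstack([c.coordinates() for c in monomer.chains])
    shift = radius * direction - all_xyz.mean(axis=0)
    placed = monomer.transform(np.eye(3), shift)
    return expand_assembly(placed, icosahedral_operators())


def make_vertex_capsid(radius: float = 30.0) -> Structure:
    """12 one-atom dummy monomers on the icosahedron vertices.

    A vertex-transitive toy assembly: every monomer touches exactly its 5
    nearest vertices at a suitable cutoff, and all 30 edges are equivalent.
    """
    chains = []
    for i, v in enumerate(icosahedron_vertices()):
        res = Residue(f"V{i:02d}", 1, "ALA",
                      [Atom(i + 1, "CB", "C", radius * v)])
        chains.append(Chain(f"V{i:02d}", [res], protomer_role="A"))
    return Structure("vertex_capsid", chains)


def make_random_structure(
    n_residues: int = 200,
    box_size: float = 60.0,
    seed: int = 0,
    chain_ids: tuple[str, ...] = ("A", "B"),
    res_pool: tuple[str, ...] = ("ARG", "LYS", "PHE", "TYR", "TRP", "HIS",
                                 "ALA", "GLY"),
) -> Structure:
    """Random scatter of idealized side chains inside a cubic box (Å).

    Residue types, positions, and orientations are drawn from a seeded
    PCG64 generator; used to exercise detection against brute-force
    oracles on irregular geometry.
    """
    rng = np.random.default_rng(seed)
    chains = {cid: Chain(cid) for cid in chain_ids}
    serial = 0
    for i in range(n_residues):
        # first residues deal round-robin so no requested chain is empty
        if i < len(chain_ids):
            cid = chain_ids[i]
        else:
            cid = chain_ids[int(rng.integers(len(chain_ids)))]
        res_name = res_pool[int(rng.integers(len(res_pool)))]
        # random rotation via QR of a Gaussian matrix, sign-fixed to det +1
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        trans = rng.uniform(0, box_size, size=3)
        seq_id = len(chains[cid].residues) + 1
        res, serial = _make_residue(res_name, cid, seq_id, serial, q, trans)
        chains[cid].residues.append(res)
    return Structure(
        f"random_{n_residues}_{seed}",
        [c for c in chains.values() if c.residues],
    )


@dataclasses.dataclass
class ParticleFieldSpec:
    """Synthetic micrograph field of virion communities.

    Defaults emulate the observed cell-extract statistics: communities of
    12 ± 4 mature virions, ~40 nm particle diameter, neighbors roughly in
    contact, communities well separated from each other.
    """

    n_communities: int = 10
    size_mean: float = 12.0
    size_sd: float = 4.0
    intra_spacing_mean: float = 45.0  # nm, member offset from community center
    intra_spacing_sd: float = 10.0
    inter_community_spacing: float = 600.0  # nm between community centers
    diameter_mean: float = 40.0  # nm
    diameter_sd: float = 2.0
    full_fraction: float = 0.377  # packaging efficiency of mature capsids
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("intra_spacing_mean", "inter_community_spacing",
                      "diameter_mean"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")


def make_particle_field(
    spec: ParticleFieldSpec,
) -> tuple[list[ParticlePick], list[int]]:
    """Seeded particle field with known community structure.

    Community centers go on a widely spaced grid; sizes are drawn from
    N(size_mean, size_sd), rounded with a floor of 2; members scatter
    around their center at radii ~ N(intra_spacing_mean, intra_spacing_sd)
    (clipped positive) and uniform angles.  Returns (picks, true sizes)
    so recovery tests can compare against ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    picks: list[ParticlePick] = []
    true_sizes: list[int] = []
    pid = 0
    grid = int(np.ceil(np.sqrt(spec.n_communities)))
    for k in range(spec.n_communities):
        cx = (k % grid) * spec.inter_community_spacing
        cy = (k // grid) * spec.inter_community_spacing
        size = max(2, int(round(rng.normal(spec.size_mean, spec.size_sd))))
        true_sizes.append(size)
        for _ in range(size):
            r = abs(rng.normal(spec.intra_spacing_mean, spec.intra_spacing_sd))
            a = rng.uniform(0, 2 * np.pi)
            pid += 1
            picks.append(
                ParticlePick(
                    particle_id=pid,
                    x=cx + r * np.cos(a),
                    y=cy + r * np.sin(a),
                    diameter=max(1.0, rng.normal(spec.diameter_mean,
                                                 spec.diameter_sd)),
                    state="full" if rng.random() < spec.full_fraction else "empty",
                )
            )
    return picks, true_sizes
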