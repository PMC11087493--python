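"""Atomic structure container, PDB/mmCIF reading, and icosahedral assembly expansion.

The in-memory model is a plain chain → residue → atom hierarchy with
coordinates in Å.  Parsing of the standard formats is delegated to gemmi;
this module owns the symmetry machinery: the 60 proper rotations of the
icosahedral group (532 orientation, two-fold axes along the coordinate
axes) and the expansion of an asymmetric unit into a full capsid.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "SymmetryOperator",
    "read_structure",
    "write_structure",
    "icosahedral_operators",
    "expand_assembly",
    "write_table",
    "read_table",
]

#: residue names treated as solvent and dropped on read
_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclasses.dataclass
class Atom:
    """One heavy (or optionally hydrogen) atom with Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.res_name = self.res_name.upper()

    @property
    def key(self) -> tuple[str, int, str]:
        """Unique identifier (chain_id, seq_id, insertion_code)."""
        return (self.chain_id, self.seq_id, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_id}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_positions(self, names: Sequence[str]) -> np.ndarray | None:
        """Positions of the named atoms in order, or None if any is missing."""
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                return None
            out.append(a.position)
        return np.array(out)


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)
    protomer_role: str = "unassigned"  # {"A", "B", "unassigned"}

    def sort_residues(self) -> None:
        self.residues.sort(key=lambda r: (r.seq_id, r.insertion_code))

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coordinates(self) -> np.ndarray:
        """All atom positions, shape (n_atoms, 3)."""
        if self.n_atoms == 0:
            return np.empty((0, 3))
        return np.vstack([a.position for r in self.residues for a in r.atoms])

    def centroid(self) -> np.ndarray:
        return self.coordinates().mean(axis=0)


@dataclasses.dataclass
class SymmetryOperator:
    """Proper rotation + translation acting on Å coordinates."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    operator_id: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("operator must be a 3x3 rotation and 3-vector translation")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthogonal (max deviation {err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det:.8f} != +1 (improper operator)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


@dataclasses.dataclass
class Structure:
    identifier: str
    chains: list[Chain] = dataclasses.field(default_factory=list)
    assembly_operators: list[SymmetryOperator] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids in structure")

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.identifier}")

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def residue(self, chain_id: str, seq_id: int, insertion_code: str = "") -> Residue:
        for r in self.chain(chain_id).residues:
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"no residue {chain_id}/{seq_id}{insertion_code}")

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-body-transformed copy (rotation then translation)."""
        op = SymmetryOperator(rotation, translation, operator_id=-1)
        out = Structure(self.identifier, [], list(self.assembly_operators))
        for c in self.chains:
            nc = Chain(c.chain_id, [], c.protomer_role)
            for r in c.residues:
                nr = Residue(r.chain_id, r.seq_id, r.res_name, [], r.insertion_code)
                for a in r.atoms:
                    nr.atoms.append(
                        Atom(a.serial, a.name, a.element, op.apply(a.position),
                             a.occupancy, a.b_factor)
                    )
                nc.residues.append(nr)
            out.chains.append(nc)
        return out


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_altlocs(raw_atoms: list[tuple[str, Atom]]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to altloc 'A'.

    ``raw_atoms`` holds (altloc, Atom) pairs for one residue.
    """
    by_name: dict[str, list[tuple[str, Atom]]] = {}
    for alt, atom in raw_atoms:
        by_name.setdefault(atom.name, []).append((alt, atom))
    kept = []
    for variants in by_name.values():
        # sort: highest occupancy first, then altloc lexicographic ('' < 'A' < 'B')
        variants.sort(key=lambda p: (-p[1].occupancy, p[0]))
        kept.append(variants[0][1])
    kept.sort(key=lambda a: a.serial)
    return kept


def read_structure(
    path: str | Path,
    fmt: str = "auto",
    include_hydrogens: bool = False,
    include_waters: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Alternate locations are collapsed to the highest-occupancy conformer
    (ties broken toward altloc 'A'); zero-occupancy atoms, waters, and
    hydrogens are dropped by default.  Assembly operators present in mmCIF
    ``_pdbx_struct_oper_list`` records are captured.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown structure format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc

    model = st[0]
    out = Structure(identifier=st.name or path.stem)
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            if not include_waters and gres.name.upper() in _WATER_NAMES:
                continue
            raw: list[tuple[str, Atom]] = []
            for ga in gres:
                if ga.occ <= 0.0:
                    continue
                if not include_hydrogens and ga.element.is_hydrogen:
                    continue
                raw.append(
                    (
                        ga.altloc or "",
                        Atom(
                            serial=ga.serial,
                            name=ga.name,
                            element=ga.element.name,
                            position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            occupancy=min(ga.occ, 1.0),
                            b_factor=ga.b_iso,
                        ),
                    )
                )
            if not raw:
                continue
            res = Residue(
                chain_id=gchain.name,
                seq_id=gres.seqid.num,
                res_name=gres.name,
                atoms=_resolve_altlocs(raw),
                insertion_code=(gres.seqid.icode or "").strip(),
            )
            chain.residues.append(res)
        if chain.residues:
            chain.sort_residues()
            out.chains.append(chain)

    out.assembly_operators = _read_assembly_operators(st)
    return out


def _read_assembly_operators(st: gemmi.Structure) -> list[SymmetryOperator]:
    ops: list[SymmetryOperator] = []
    for assembly in st.assemblies:
        for gen in assembly.generators:
            for oper in gen.operators:
                t = oper.transform
                rot = np.array([[t.mat[i][j] for j in range(3)] for i in range(3)])
                vec = np.array([t.vec.x, t.vec.y, t.vec.z])
                try:
                    ops.append(SymmetryOperator(rot, vec, operator_id=len(ops)))
                except ValueError:
                    continue  # skip improper/degenerate operators
        if ops:
            break  # first (usually biological) assembly only
    return ops


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as fixed-column PDB."""
    st = gemmi.Structure()
    st.name = s.identifier
    model = gemmi.Model("1")
    serial = 0
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                serial += 1
                ga.serial = serial
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# icosahedral symmetry

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def icosahedron_vertices() -> np.ndarray:
    """The 12 unit vertex directions of the icosahedron in 532/222 orientation.

    Vertices are the cyclic permutations of (0, ±1, ±φ) normalised; the
    two-fold axes of the solid lie along the coordinate axes.
    """
    v = []
    for a, b in [(1, _PHI), (-1, _PHI), (1, -_PHI), (-1, -_PHI)]:
        v.append([0, a, b])
        v.append([b, 0, a])
        v.append([a, b, 0])
    v = np.array(v, dtype=float)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def icosahedral_operators() -> list[SymmetryOperator]:
    """The 60 proper rotations of the icosahedral group I.

    Standard 532 orientation: two-fold axes along x, y, z; five-fold axes
    through the icosahedron vertices (0, ±1, ±φ) and permutations.  The
    group is generated by closure from a five-fold and a two-fold
    generator; the identity carries operator_id 0 and the remaining
    elements are ordered by a deterministic lexicographic key on the
    rounded matrix entries.
    """
    five = _rotation_about(np.array([0.0, 1.0, _PHI]), 2 * np.pi / 5)
    two = _rotation_about(np.array([0.0, 0.0, 1.0]), np.pi)

    def key(m: np.ndarray) -> tuple:
        return tuple(np.round(m, 9).ravel())

    elements: dict[tuple, np.ndarray] = {key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in (five, two):
                p = g @ m
                k = key(p)
                if k not in elements:
                    elements[k] = p
                    nxt.append(p)
        frontier = nxt
    mats = list(elements.values())
    assert len(mats) == 60, f"icosahedral closure produced {len(mats)} elements"
    # identity first, rest in deterministic order
    mats.sort(key=lambda m: (np.abs(m - np.eye(3)).max() > 1e-9, key(m)))
    return [
        SymmetryOperator(m, np.zeros(3), operator_id=i) for i, m in enumerate(mats)
    ]


def operator_suffix(operator_id: int) -> str:
    return f"_op{operator_id:02d}"


def strip_operator_suffix(chain_id: str) -> tuple[str, int | None]:
    """Split "B_op07" into ("B", 7); plain ids return (id, None)."""
    if "_op" in chain_id:
        base, _, tail = chain_id.rpartition("_op")
        if tail.isdigit():
            return base, int(tail)
    return chain_id, None


def expand_assembly(s: Structure, ops: Sequence[SymmetryOperator]) -> Structure:
    """Apply each symmetry operator to every chain, producing the assembly.

    Chain copies are named ``<original>_opNN`` (NN zero-padded operator id);
    protomer roles are inherited.  With the 60 icosahedral operators a
    2-chain asymmetric unit yields the 120 protomer chains of a T=1 capsid.
    """
    if not ops:
        raise ValueError("operator list is empty")
    if not s.chains:
        raise ValueError("structure has no chains")
    out = Structure(identifier=f"{s.identifier}_assembly")
    serial = 0
    for op in ops:
        for chain in s.chains:
            nc = Chain(
                chain_id=chain.chain_id + operator_suffix(op.operator_id),
                protomer_role=chain.protomer_role,
            )
            for res in chain.residues:
                nr = Residue(nc.chain_id, res.seq_id, res.res_name, [],
                             res.insertion_code)
                for atom in res.atoms:
                    serial += 1
                    nr.atoms.append(
                        Atom(serial, atom.name, atom.element,
                             op.apply(atom.position), atom.occupancy,
                             atom.b_factor)
                    )
                nc.residues.append(nr)
            out.chains.append(nc)
    return out


# ---------------------------------------------------------------------------
# tabular output

def _records_to_frame(records: Iterable) -> pd.DataFrame:
    records = list(records)
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, dict):
            rows.append(rec)
        else:
            raise TypeError(f"cannot tabulate record of type {type(rec)}")
    return pd.DataFrame(rows)


def write_table(records: Iterable, path: str | Path, fmt: str = "tsv",
                columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as TSV ('.' decimal) or JSON.

    An empty record list with explicit ``columns`` produces a header-only
    table; column order is the record field order (deterministic).
    """
    df = _records_to_frame(records)
    if df.empty and columns is not None:
        df = pd.DataFrame(columns=list(columns))
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown table format {fmt!r}")


def read_table(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unknown table format {fmt!r}")
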