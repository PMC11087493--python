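"""Geometric detection of cation-π interactions.

A cation-π contact is recorded when the charge center of a cationic side
chain (Arg guanidinium, Lys ammonium, optionally His imidazolium) lies
within ``d_max`` of an aromatic ring centroid (Phe/Tyr six-ring, both Trp
rings, optionally His) AND the centroid→cation vector is within
``theta_max`` of the ring normal — i.e. the cation sits over the π face
rather than in the ring plane.  The default distance threshold is 5 Å;
the default acceptance cone is 45° from the normal, the conventional
cutoff in the cation-π literature.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure, strip_operator_suffix

logger = logging.getLogger(__name__)

__all__ = [
    "AromaticRing",
    "CationSite",
    "DetectionParams",
    "CationPiContact",
    "ring_geometry",
    "cation_sites",
    "detect_contacts",
    "classify_contact",
    "contact_records",
]

#: ring member atom names per residue type
RING_ATOMS: dict[str, list[tuple[str, list[str]]]] = {
    "PHE": [("PHE6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TYR": [("TYR6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TRP": [
        ("TRP5", ["CG", "CD1", "CD2", "NE1", "CE2"]),
        ("TRP6", ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]),
    ],
    "HIS": [("HIS5", ["CG", "ND1", "CD2", "CE1", "NE2"])],
}


@dataclasses.dataclass
class AromaticRing:
    residue_ref: tuple[str, int, str]
    res_name: str
    ring_label: str  # PHE6 | TYR6 | TRP5 | TRP6 | HIS5
    member_atom_names: list[str]
    centroid: np.ndarray
    normal: np.ndarray  # unit vector
    planarity_rms: float


@dataclasses.dataclass
class CationSite:
    residue_ref: tuple[str, int, str]
    res_name: str
    site_label: str  # ARG_GUA | LYS_NZ | HIS_IMD
    charge_center: np.ndarray


@dataclasses.dataclass
class DetectionParams:
    """Thresholds and flags for the geometric cation-π rule."""

    d_max: float = 5.0  # Å, centroid–charge-center distance
    theta_max: float = 45.0  # degrees from the ring normal
    include_his_cation: bool = False
    include_his_ring: bool = False
    neighbor_cell_size: float = 6.0  # Å, spatial-index bin size

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_max <= 90:
            raise ValueError("theta_max must lie in (0, 90]")


@dataclasses.dataclass
class CationPiContact:
    cation: CationSite
    ring: AromaticRing
    distance: float  # Å
    theta: float  # degrees, folded into [0, 90]
    chain_pair: tuple[str, str] = ("", "")
    scope: str = "unclassified"  # intra_chain | inter_chain
    symmetry_related: bool = False


def _plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through points: (centroid, unit normal, rms).

    The normal is the eigenvector of the centered covariance with the
    smallest eigenvalue; rms is the out-of-plane root-mean-square residual.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]
    rms = float(np.sqrt(max(eigvals[0], 0.0) / len(points)))
    return centroid, normal, rms


def ring_geometry(r: Residue, include_his_ring: bool = False) -> list[AromaticRing]:
    """Aromatic ring(s) of a residue: centroid, least-squares normal, planarity.

    Trp contributes its five- and six-membered rings separately; His is
    included only on request (protonation in the model is unknown).
    Residues with missing ring atoms are skipped with a warning.
    """
    specs = RING_ATOMS.get(r.res_name)
    if specs is None or (r.res_name == "HIS" and not include_his_ring):
        return []
    rings = []
    for label, names in specs:
        pts = r.atom_positions(names)
        if pts is None:
            logger.warning("residue %s missing ring atoms for %s; skipped",
                           r.label, label)
            continue
        centroid, normal, rms = _plane_fit(pts)
        rings.append(
            AromaticRing(r.key, r.res_name, label, list(names), centroid,
                         normal, rms)
        )
    return rings


def cation_sites(r: Residue, include_his_cation: bool = False) -> list[CationSite]:
    """Cationic side-chain charge center of a residue, if any.

    Arg → CZ (symmetry center of the delocalised guanidinium), Lys → NZ,
    His (on request) → midpoint of ND1/NE2.
    """
    if r.res_name == "ARG":
        a = r.atom("CZ")
        if a is None:
            logger.warning("ARG %s missing CZ; skipped", r.label)
            return []
        return [CationSite(r.key, r.res_name, "ARG_GUA", a.position)]
    if r.res_name == "LYS":
        a = r.atom("NZ")
        if a is None:
            logger.warning("LYS %s missing NZ; skipped", r.label)
            return []
        return [CationSite(r.key, r.res_name, "LYS_NZ", a.position)]
    if r.res_name == "HIS" and include_his_cation:
        pts = r.atom_positions(["ND1", "NE2"])
        if pts is None:
            logger.warning("HIS %s missing imidazole nitrogens; skipped", r.label)
            return []
        return [CationSite(r.key, r.res_name, "HIS_IMD", pts.mean(axis=0))]
    return []


def _contact_angle(ring: AromaticRing, cation: CationSite) -> tuple[float, float]:
    """(distance, theta°) between a ring and a cation site.

    theta is measured from the ring normal to the centroid→cation vector
    and folded into [0°, 90°] (rings are two-sided).
    """
    vec = cation.charge_center - ring.centroid
    dist = float(np.linalg.norm(vec))
    if dist == 0.0:
        return 0.0, 0.0
    cos_t = abs(float(np.dot(vec / dist, ring.normal)))
    theta = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
    return dist, theta


def _collect_sites(
    s: Structure, p: DetectionParams
) -> tuple[list[CationSite], list[AromaticRing]]:
    cations: list[CationSite] = []
    rings: list[AromaticRing] = []
    for res in s.residues():
        cations.extend(cation_sites(res, p.include_his_cation))
        rings.extend(ring_geometry(res, p.include_his_ring))
    return cations, rings


def _evaluate_pair(
    cation: CationSite, ring: AromaticRing, p: DetectionParams
) -> CationPiContact | None:
    if cation.residue_ref == ring.residue_ref:
        return None
    dist, theta = _contact_angle(ring, cation)
    if dist <= p.d_max and theta <= p.theta_max:
        return CationPiContact(cation, ring, dist, theta)
    return None


def _sort_key(c: CationPiContact) -> tuple:
    return (c.cation.residue_ref, c.ring.residue_ref, c.ring.ring_label)


def detect_contacts(
    s: Structure,
    p: DetectionParams | None = None,
    deduplicate_symmetry: bool = False,
) -> list[CationPiContact]:
    """All cation-π contacts of a structure under the geometric rule.

    Candidate ring/cation pairs come from a k-d-tree radius query over
    ring centroids (bounded by ``d_max``), so the search scales near
    linearly; the emitted set is identical to an all-pairs scan.  Output
    is sorted by (cation residue, ring residue, ring label) and each
    contact carries its chain-pair classification.

    With ``deduplicate_symmetry`` (for symmetry-expanded assemblies),
    contacts equivalent under the ``_opNN`` copy naming are reported once,
    keyed by the lexicographically smallest (operator, residue) pair.
    """
    p = p or DetectionParams()
    cations, rings = _collect_sites(s, p)
    contacts: list[CationPiContact] = []
    if cations and rings:
        centroids = np.array([r.centroid for r in rings])
        tree = cKDTree(centroids)
        charge_centers = np.array([c.charge_center for c in cations])
        for ci, neighbor_idx in enumerate(
            tree.query_ball_point(charge_centers, r=p.d_max)
        ):
            for ri in neighbor_idx:
                contact = _evaluate_pair(cations[ci], rings[ri], p)
                if contact is not None:
                    contacts.append(classify_contact(contact, s))
    if deduplicate_symmetry:
        contacts = _deduplicate_symmetry_copies(contacts)
    contacts.sort(key=_sort_key)
    return contacts


def detect_contacts_brute_force(
    s: Structure, p: DetectionParams | None = None
) -> list[CationPiContact]:
    """O(n²) all-pairs reference scan with the identical geometric rule."""
    p = p or DetectionParams()
    cations, rings = _collect_sites(s, p)
    contacts = []
    for cation in cations:
        for ring in rings:
            contact = _evaluate_pair(cation, ring, p)
            if contact is not None:
                contacts.append(classify_contact(contact, s))
    contacts.sort(key=_sort_key)
    return contacts


def classify_contact(c: CationPiContact, s: Structure | None = None) -> CationPiContact:
    """Fill scope / chain pair / symmetry flag from the residue chain ids.

    Scope is intra-chain iff both residues share a chain id after the
    ``_opNN`` copy suffix is stripped the pair is additionally flagged
    symmetry-related when the operator suffixes differ.
    """
    chain_c, chain_r = c.cation.residue_ref[0], c.ring.residue_ref[0]
    if s is not None:  # validate references are resolvable
        s.chain(chain_c)
        s.chain(chain_r)
    base_c, op_c = strip_operator_suffix(chain_c)
    base_r, op_r = strip_operator_suffix(chain_r)
    c.chain_pair = (chain_c, chain_r)
    c.scope = "intra_chain" if chain_c == chain_r else "inter_chain"
    c.symmetry_related = op_c != op_r
    return c


def _deduplicate_symmetry_copies(
    contacts: list[CationPiContact],
) -> list[CationPiContact]:
    """Report each asymmetric-unit-unique contact once.

    The canonical key maps both residues to their base chain / seq id and
    keeps the operator *difference* structure by choosing the contact with
    the lexicographically smallest (operator, operator) pair per key.
    """
    best: dict[tuple, tuple[tuple, CationPiContact]] = {}
    for c in contacts:
        base_c, op_c = strip_operator_suffix(c.cation.residue_ref[0])
        base_r, op_r = strip_operator_suffix(c.ring.residue_ref[0])
        key = (
            base_c, c.cation.residue_ref[1:], base_r, c.ring.residue_ref[1:],
            c.ring.ring_label,
        )
        rank = (op_c if op_c is not None else -1, op_r if op_r is not None else -1)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, c)
    return [pair[1] for pair in best.values()]


def contact_records(contacts: Sequence[CationPiContact]) -> list[dict]:
    """Flatten contacts into TSV-ready rows (deterministic column order)."""
    rows = []
    for c in contacts:
        rows.append(
            {
                "cation_chain": c.cation.residue_ref[0],
                "cation_resid": c.cation.residue_ref[1],
                "cation_resname": c.cation.res_name,
                "site_label": c.cation.site_label,
                "ring_chain": c.ring.residue_ref[0],
                "ring_resid": c.ring.residue_ref[1],
                "ring_resname": c.ring.res_name,
                "ring_label": c.ring.ring_label,
                "distance_A": round(c.distance, 4),
                "theta_deg": round(c.theta, 3),
                "scope": c.scope,
                "symmetry_related": c.symmetry_related,
            }
        )
    return rows

CONTACT_COLUMNS = [
    "cation_chain", "cation_resid", "cation_resname", "site_label",
    "ring_chain", "ring_resid", "ring_resname", "ring_label",
    "distance_A", "theta_deg", "scope", "symmetry_related",
]
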