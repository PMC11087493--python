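"""Grouping of cation-π contacts into residue interaction networks.

Networks are the connected components of the residue graph whose edges are
detected contacts: a chain of contacts Arg–Tyr, Tyr–Trp therefore forms a
single three-residue network.  This is the statistic behind per-structure
summaries such as "N side chains in M distinct networks".
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx

from .catpi_detect import CationPiContact

__all__ = [
    "InteractionNetwork",
    "NetworkSummary",
    "build_networks",
    "summarize_networks",
    "network_records",
]


@dataclasses.dataclass
class InteractionNetwork:
    network_id: int
    residues: set  # of residue identifiers (chain_id, seq_id, icode)
    contacts: list[CationPiContact]
    scope_summary: str  # intra_chain | inter_chain | mixed


@dataclasses.dataclass
class NetworkSummary:
    n_networks: int
    n_side_chains: int
    per_network_sizes: list[int]


def build_networks(contacts: Sequence[CationPiContact]) -> list[InteractionNetwork]:
    """Connected components of the contact graph, deterministically ordered.

    Nodes are residues, edges are contacts; network ids are assigned in
    order of each component's smallest member residue.
    """
    g = nx.Graph()
    for c in contacts:
        g.add_edge(c.cation.residue_ref, c.ring.residue_ref)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda members: members[0],
    )
    networks = []
    for nid, members in enumerate(components):
        member_set = set(members)
        net_contacts = [
            c for c in contacts
            if c.cation.residue_ref in member_set and c.ring.residue_ref in member_set
        ]
        scopes = {c.scope for c in net_contacts}
        if scopes <= {"intra_chain"}:
            scope_summary = "intra_chain"
        elif scopes <= {"inter_chain"}:
            scope_summary = "inter_chain"
        else:
            scope_summary = "mixed"
        networks.append(InteractionNetwork(nid, member_set, net_contacts, scope_summary))
    return networks


def summarize_networks(nets: Sequence[InteractionNetwork]) -> NetworkSummary:
    """Counts of networks and of distinct participating side chains."""
    all_residues = set().union(*(n.residues for n in nets)) if nets else set()
    return NetworkSummary(
        n_networks=len(nets),
        n_side_chains=len(all_residues),
        per_network_sizes=[len(n.residues) for n in nets],
    )


def network_records(nets: Sequence[InteractionNetwork]) -> list[dict]:
    rows = []
    for n in nets:
        members = sorted(n.residues)
        rows.append(
            {
                "network_id": n.network_id,
                "size": len(members),
                "residues": ";".join(f"{c}:{s}{i}" for c, s, i in members),
                "scope_summary": n.scope_summary,
            }
        )
    return rows

NETWORK_COLUMNS = ["network_id", "size", "residues", "scope_summary"]
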