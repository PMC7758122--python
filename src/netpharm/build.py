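"""Assembly of the compound-target (CTN), target-pathway (TPN) and combined
compound-target-pathway (CTPN) networks, plus per-class summary statistics.

Nodes with no surviving edge are never materialised: a compound whose every
docking/database interaction was filtered out simply does not appear in the
CTN, and a target with no KEGG pathway does not appear in the TPN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import InteractionEdge, PathwayMembership, TypedNetwork

__all__ = [
    "NetworkSummary",
    "build_ctn",
    "build_tpn",
    "build_ctpn",
    "summarize",
    "CT_PAIR",
    "TP_PAIR",
]

CT_PAIR = frozenset({"compound", "target"})
TP_PAIR = frozenset({"target", "pathway"})


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_compounds: int
    n_targets: int
    n_pathways: int
    n_edges: int

    def __post_init__(self) -> None:
        if self.n_nodes != self.n_compounds + self.n_targets + self.n_pathways:
            raise ValueError("node counts do not add up")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_nodes": self.n_nodes,
            "n_compounds": self.n_compounds,
            "n_targets": self.n_targets,
            "n_pathways": self.n_pathways,
            "n_edges": self.n_edges,
        }


def build_ctn(edges: Sequence[InteractionEdge]) -> TypedNetwork:
    """Bipartite compound-target network from a deduplicated edge list."""
    net = TypedNetwork(allowed_pairs={CT_PAIR})
    seen: set[tuple[str, str]] = set()
    for e in edges:
        if e.pair in seen:
            raise ValueError(f"duplicate interaction edge {e.pair}")
        seen.add(e.pair)
        net.add_node(e.compound_abbrev, "compound")
        net.add_node(e.uniprot_ac, "target")
        net.add_edge(e.compound_abbrev, e.uniprot_ac)
    return net


def build_tpn(
    members: Sequence[PathwayMembership],
    target_whitelist: Iterable[str],
) -> TypedNetwork:
    """Bipartite target-pathway network restricted to whitelisted targets.

    The whitelist is normally the target set of the CTN, so only proteins the
    preparation actually touches contribute pathway links.
    """
    whitelist = set(target_whitelist)
    net = TypedNetwork(allowed_pairs={TP_PAIR})
    for m in members:
        if m.uniprot_ac not in whitelist:
            continue
        net.add_node(m.uniprot_ac, "target")
        net.add_node(m.pathway_id, "pathway")
        net.add_edge(m.uniprot_ac, m.pathway_id)
    return net


def build_ctpn(
    ctn: TypedNetwork,
    tpn: TypedNetwork,
    selected_pathways: Iterable[str],
) -> TypedNetwork:
    """Tripartite network induced by a set of selected pathways.

    Keeps the selected pathways, the targets linked to them in the TPN, the
    compounds linked to those targets in the CTN, and the induced
    compound-target and target-pathway edges. Compounds whose every target
    fell outside the selection are dropped.
    """
    selected = set(selected_pathways)
    tpn_pathways = set(tpn.nodes("pathway"))
    missing = selected - tpn_pathways
    if missing:
        raise ValueError(f"selected pathway(s) absent from TPN: {sorted(missing)}")
    net = TypedNetwork(allowed_pairs={CT_PAIR, TP_PAIR})
    kept_targets: set[str] = set()
    for p in sorted(selected):
        net.add_node(p, "pathway")
        for t in tpn.neighbors(p):
            kept_targets.add(t)
            net.add_node(t, "target")
            net.add_edge(t, p)
    for t in sorted(kept_targets):
        if t not in ctn:
            continue
        for c in ctn.neighbors(t):
            if c not in net:
                net.add_node(c, "compound")
            if not net.has_edge(c, t):
                net.add_edge(c, t)
    return net


def summarize(net: TypedNetwork) -> NetworkSummary:
    """Exact node counts by class plus the edge count."""
    n_c = len(net.nodes("compound"))
    n_t = len(net.nodes("target"))
    n_p = len(net.nodes("pathway"))
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_compounds=n_c,
        n_targets=n_t,
        n_pathways=n_p,
        n_edges=net.n_edges,
    )
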