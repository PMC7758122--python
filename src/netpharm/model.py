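"""Domain types for compound-target-pathway network pharmacology.

Node identity conventions follow the field's usage: compounds are keyed by
their short abbreviation, protein targets by UniProt accession, and pathways
by KEGG map identifier (``hsaNNNNN``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "Compound",
    "DockingRecord",
    "InteractionEdge",
    "PathwayMembership",
    "TypedNetwork",
    "NODE_CLASSES",
    "UNIPROT_AC_RE",
    "KEGG_PATHWAY_RE",
    "validate_compounds",
]

NODE_CLASSES = ("compound", "target", "pathway")

#: UniProt accession grammar (canonical 6- and 10-character forms).
UNIPROT_AC_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

#: KEGG human pathway map identifier, e.g. hsa04064.
KEGG_PATHWAY_RE = re.compile(r"^hsa[0-9]+$")


@dataclass(frozen=True)
class Compound:
    """An ingredient or metabolite of a multi-component preparation.

    ``content_mg_per_ml`` is the measured content in the injection;
    metabolites have no direct content and carry the parent compound's
    abbreviation in ``metabolite_of``.
    """

    abbrev: str
    name: str
    mw: float
    cas: Optional[str] = None
    pubchem_cid: Optional[int] = None
    content_mg_per_ml: Optional[float] = None
    metabolite_of: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.abbrev:
            raise ValueError("compound abbrev must be non-empty")
        if not self.mw > 0:
            raise ValueError(f"compound {self.abbrev!r}: mw must be > 0, got {self.mw}")
        if self.content_mg_per_ml is not None and self.content_mg_per_ml < 0:
            raise ValueError(f"compound {self.abbrev!r}: negative content")

    @property
    def is_metabolite(self) -> bool:
        return self.metabolite_of is not None


def validate_compounds(compounds: Iterable[Compound]) -> list[Compound]:
    """Enforce table-level invariants: unique abbrevs, resolvable parents."""
    compounds = list(compounds)
    seen: set[str] = set()
    for c in compounds:
        if c.abbrev in seen:
            raise ValueError(f"duplicate compound abbrev: {c.abbrev!r}")
        seen.add(c.abbrev)
    for c in compounds:
        if c.metabolite_of is not None and c.metabolite_of not in seen:
            raise ValueError(
                f"compound {c.abbrev!r}: metabolite_of {c.metabolite_of!r} "
                "does not match any abbrev in the table"
            )
    return compounds


@dataclass(frozen=True)
class DockingRecord:
    """One compound-protein docking result (best-pose binding energy, kcal/mol)."""

    compound_abbrev: str
    target_name: str
    uniprot_ac: str
    binding_energy: float

    def __post_init__(self) -> None:
        if not UNIPROT_AC_RE.match(self.uniprot_ac):
            raise ValueError(f"invalid UniProt accession: {self.uniprot_ac!r}")


EVIDENCE_KINDS = ("database", "docking")


@dataclass(frozen=True)
class InteractionEdge:
    """An evidenced compound-target interaction."""

    compound_abbrev: str
    uniprot_ac: str
    evidence: str
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(
                f"evidence must be one of {EVIDENCE_KINDS}, got {self.evidence!r}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.compound_abbrev, self.uniprot_ac)


@dataclass(frozen=True)
class PathwayMembership:
    """A target's membership in a KEGG pathway."""

    uniprot_ac: str
    pathway_id: str
    pathway_name: str = ""

    def __post_init__(self) -> None:
        if not KEGG_PATHWAY_RE.match(self.pathway_id):
            raise ValueError(f"invalid KEGG pathway id: {self.pathway_id!r}")


class TypedNetwork:
    """Undirected graph whose nodes carry a class label.

    Self-loops and duplicate edges are rejected; an optional set of allowed
    class pairs restricts which layers may be joined (compound-target for a
    CTN, target-pathway for a TPN, both for a CTPN).
    """

    def __init__(self, allowed_pairs: Optional[set[frozenset[str]]] = None) -> None:
        self._classes: dict[str, str] = {}
        self._adj: dict[str, set[str]] = {}
        self._edges: set[frozenset[str]] = set()
        self.allowed_pairs = allowed_pairs

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, node_class: str) -> None:
        if node_class not in NODE_CLASSES:
            raise ValueError(f"unknown node class {node_class!r}")
        existing = self._classes.get(node_id)
        if existing is not None and existing != node_class:
            raise ValueError(
                f"node {node_id!r} already present with class {existing!r}"
            )
        self._classes[node_id] = node_class
        self._adj.setdefault(node_id, set())

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        for x in (u, v):
            if x not in self._classes:
                raise ValueError(f"edge endpoint {x!r} is not a node")
        pair = frozenset((self._classes[u], self._classes[v]))
        if self.allowed_pairs is not None and pair not in self.allowed_pairs:
            raise ValueError(
                f"edge {u!r}-{v!r} joins classes {sorted(pair)}, "
                "not allowed in this network"
            )
        key = frozenset((u, v))
        if key in self._edges:
            raise ValueError(f"duplicate edge {u!r}-{v!r}")
        self._edges.add(key)
        self._adj[u].add(v)
        self._adj[v].add(u)

    # -- queries -----------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._classes

    def __len__(self) -> int:
        return len(self._classes)

    @property
    def n_nodes(self) -> int:
        return len(self._classes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def nodes(self, node_class: Optional[str] = None) -> list[str]:
        """Node ids in deterministic (sorted) order, optionally one class."""
        if node_class is None:
            return sorted(self._classes)
        return sorted(n for n, c in self._classes.items() if c == node_class)

    def node_class(self, node_id: str) -> str:
        return self._classes[node_id]

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) tuples in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self._edges)

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self._edges

    def neighbors(self, node_id: str) -> list[str]:
        return sorted(self._adj[node_id])

    def degree(self, node_id: str) -> int:
        return len(self._adj[node_id])

    def node_set(self) -> set[tuple[str, str]]:
        return {(n, c) for n, c in self._classes.items()}

    def edge_set(self) -> set[frozenset[str]]:
        return set(self._edges)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._classes))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypedNetwork):
            return NotImplemented
        return self.node_set() == other.node_set() and self._edges == other._edges

    def copy(self) -> "TypedNetwork":
        out = TypedNetwork(allowed_pairs=self.allowed_pairs)
        for n, c in self._classes.items():
            out.add_node(n, c)
        for u, v in self.edges():
            out.add_edge(u, v)
        return out
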