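"""Readers and writers for the tabular inputs and network exports.

All tables are UTF-8 CSV with a header row; a tab-delimited variant is
accepted for transcriptions of printed tables (``sep="\\t"``). Network
exports cover SIF and GraphML (both loadable by Cytoscape) plus a plain
edge-CSV that round-trips node classes exactly.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    Compound,
    DockingRecord,
    InteractionEdge,
    PathwayMembership,
    TypedNetwork,
    validate_compounds,
)

__all__ = [
    "read_compound_table",
    "read_docking_table",
    "read_interaction_edges",
    "read_pathway_memberships",
    "write_network",
    "read_network",
]

PathLike = Union[str, Path]

_MISSING = {"", "NA"}


def _cell(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in _MISSING else value


def _numeric(value: str, row: int, column: str) -> Optional[float]:
    cell = _cell(value)
    if cell is None:
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"malformed numeric cell in column {column!r}, data row {row}: {value!r}"
        ) from None


def _read_raw(path: PathLike, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


def read_compound_table(path: PathLike, sep: str = ",") -> list[Compound]:
    """Read a compound table; ``NA``/empty cells map to absent fields.

    Columns: abbrev, name, cas, pubchem_cid, mw, content_mg_per_ml,
    metabolite_of. Row order is preserved; duplicate abbrevs and dangling
    ``metabolite_of`` references are hard errors.
    """
    df = _read_raw(path, sep)
    required = {"abbrev", "name", "mw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    compounds = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        cid = _numeric(rec.get("pubchem_cid", ""), i, "pubchem_cid")
        mw = _numeric(rec["mw"], i, "mw")
        if mw is None:
            raise ValueError(f"missing mw in data row {i}")
        compounds.append(
            Compound(
                abbrev=_cell(rec["abbrev"]) or "",
                name=_cell(rec["name"]) or "",
                mw=mw,
                cas=_cell(rec.get("cas", "")),
                pubchem_cid=int(cid) if cid is not None else None,
                content_mg_per_ml=_numeric(rec.get("content_mg_per_ml", ""), i, "content_mg_per_ml"),
                metabolite_of=_cell(rec.get("metabolite_of", "")),
            )
        )
    return validate_compounds(compounds)


def read_docking_table(path: PathLike, sep: str = ",") -> list[DockingRecord]:
    """Read a docking-result table in the printed-table dialect.

    The compound column may be blank on continuation rows, in which case the
    last seen compound label is carried down (the printed table names each
    compound once per block of rows).
    """
    df = _read_raw(path, sep)
    required = {"compound", "target_name", "uniprot_ac", "binding_energy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"docking table missing columns: {sorted(missing)}")
    records = []
    current: Optional[str] = None
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        label = _cell(rec["compound"])
        if label is not None:
            current = label
        if current is None:
            raise ValueError(f"data row {i} has no compound label to carry down")
        energy = _numeric(rec["binding_energy"], i, "binding_energy")
        if energy is None:
            raise ValueError(f"missing binding_energy in data row {i}")
        records.append(
            DockingRecord(
                compound_abbrev=current,
                target_name=_cell(rec["target_name"]) or "",
                uniprot_ac=_cell(rec["uniprot_ac"]) or "",
                binding_energy=energy,
            )
        )
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.compound_abbrev, r.uniprot_ac)
        if key in seen:
            raise ValueError(f"duplicate docking record for {key}")
        seen.add(key)
    return records


def read_interaction_edges(path: PathLike, sep: str = ",") -> list[InteractionEdge]:
    """Read a known compound-target edge list.

    Columns: compound_abbrev, uniprot_ac, optional evidence (default
    ``database``) and source_label.
    """
    df = _read_raw(path, sep)
    required = {"compound_abbrev", "uniprot_ac"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    edges = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        edges.append(
            InteractionEdge(
                compound_abbrev=_cell(rec["compound_abbrev"]) or "",
                uniprot_ac=_cell(rec["uniprot_ac"]) or "",
                evidence=_cell(rec.get("evidence", "")) or "database",
                source_label=_cell(rec.get("source_label", "")) or "",
            )
        )
    return edges


def read_pathway_memberships(path: PathLike, sep: str = ",") -> list[PathwayMembership]:
    """Read a target-pathway membership list (uniprot_ac, pathway_id, pathway_name)."""
    df = _read_raw(path, sep)
    required = {"uniprot_ac", "pathway_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"membership table missing columns: {sorted(missing)}")
    members = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        rec = row._asdict()
        m = PathwayMembership(
            uniprot_ac=_cell(rec["uniprot_ac"]) or "",
            pathway_id=_cell(rec["pathway_id"]) or "",
            pathway_name=_cell(rec.get("pathway_name", "")) or "",
        )
        key = (m.uniprot_ac, m.pathway_id)
        if key in seen:
            raise ValueError(f"duplicate pathway membership {key}")
        seen.add(key)
        members.append(m)
    return members


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "edge-csv")


def write_network(net: TypedNetwork, path: PathLike, format: str = "graphml") -> None:
    """Write a network in SIF, GraphML or edge-CSV form.

    SIF carries the ordered class pair as the interaction label (e.g.
    ``compound-target``); GraphML stores the node class as a node attribute
    and round-trips exactly; edge-CSV writes one row per edge with the class
    of both endpoints.
    """
    path = Path(path)
    if format == "sif":
        _write_sif(net, path)
    elif format == "graphml":
        _write_graphml(net, path)
    elif format == "edge-csv":
        _write_edge_csv(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}; use one of {NETWORK_FORMATS}")


def read_network(path: PathLike, format: str = "graphml") -> TypedNetwork:
    path = Path(path)
    if format == "graphml":
        return _read_graphml(path)
    if format == "edge-csv":
        return _read_edge_csv(path)
    raise ValueError(f"unknown network format {format!r}; readable: graphml, edge-csv")


_CLASS_ORDER = {"compound": 0, "target": 1, "pathway": 2}


def _ordered_endpoints(net: TypedNetwork, u: str, v: str) -> tuple[str, str]:
    cu, cv = net.node_class(u), net.node_class(v)
    if (_CLASS_ORDER[cu], u) <= (_CLASS_ORDER[cv], v):
        return u, v
    return v, u


def _write_sif(net: TypedNetwork, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for u, v in net.edges():
            a, b = _ordered_endpoints(net, u, v)
            label = f"{net.node_class(a)}-{net.node_class(b)}"
            fh.write(f"{a}\t{label}\t{b}\n")


def _write_graphml(net: TypedNetwork, path: Path) -> None:
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    key = ET.SubElement(root, f"{{{ns}}}key")
    key.set("id", "d0")
    key.set("for", "node")
    key.set("attr.name", "node_class")
    key.set("attr.type", "string")
    graph = ET.SubElement(root, f"{{{ns}}}graph")
    graph.set("edgedefault", "undirected")
    for n in net.nodes():
        el = ET.SubElement(graph, f"{{{ns}}}node", id=n)
        data = ET.SubElement(el, f"{{{ns}}}data", key="d0")
        data.text = net.node_class(n)
    for u, v in net.edges():
        ET.SubElement(graph, f"{{{ns}}}edge", source=u, target=v)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _read_graphml(path: Path) -> TypedNetwork:
    ns = "{http://graphml.graphdrawing.org/xmlns}"
    root = ET.parse(path).getroot()
    graph = root.find(f"{ns}graph")
    if graph is None:
        raise ValueError(f"{path}: no <graph> element")
    net = TypedNetwork()
    for el in graph.findall(f"{ns}node"):
        data = el.find(f"{ns}data")
        if data is None or not data.text:
            raise ValueError(f"{path}: node {el.get('id')!r} lacks node_class")
        net.add_node(el.get("id"), data.text.strip())
    for el in graph.findall(f"{ns}edge"):
        net.add_edge(el.get("source"), el.get("target"))
    return net


def _write_edge_csv(net: TypedNetwork, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "source_class", "target", "target_class"])
        for u, v in net.edges():
            a, b = _ordered_endpoints(net, u, v)
            writer.writerow([a, net.node_class(a), b, net.node_class(b)])


def _read_edge_csv(path: Path) -> TypedNetwork:
    net = TypedNetwork()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            for node, cls in ((row["source"], row["source_class"]),
                              (row["target"], row["target_class"])):
                if node not in net:
                    net.add_node(node, cls)
            net.add_edge(row["source"], row["target"])
    return net
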