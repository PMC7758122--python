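"""Topology-based screening of key targets and important pathways, plus the
curated pathway cross-talk fixture.

Targets are screened on the compound-target network by two conjunctive
criteria: degree in the top ten of all targets (ties at the boundary value
included), and betweenness and closeness both strictly above the mean over
the target class. Pathways are screened on the target-pathway network by a
cascade: degree strictly above a cut-off (default 6), betweenness above the
pathway-class mean, removal of pathways that do not name a specific
biological process, then closeness above the class mean. Every candidate is
audited so the stage at which it dropped out is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .centrality import class_mean

__all__ = [
    "TargetCriteria",
    "PathwayCriteria",
    "ScreeningResult",
    "CrosstalkEdge",
    "screen_key_targets",
    "screen_important_pathways",
    "load_crosstalk",
    "validate_crosstalk",
    "DEFAULT_NONSPECIFIC_BLOCKLIST",
    "CROSSTALK_PATHWAYS",
    "HUB_PATHWAY",
]

#: Pathway names excluded as not representing a specific biological process.
DEFAULT_NONSPECIFIC_BLOCKLIST = frozenset(
    {
        "metabolic pathways",
        "pathways in cancer",
        "neuroactive ligand-receptor interaction",
        "micrornas in cancer",
    }
)


@dataclass(frozen=True)
class TargetCriteria:
    top_k_degree: int = 10
    require_betweenness_above_mean: bool = True
    require_closeness_above_mean: bool = True

    def __post_init__(self) -> None:
        if self.top_k_degree < 1:
            raise ValueError("top_k_degree must be >= 1")


@dataclass(frozen=True)
class PathwayCriteria:
    min_degree_exclusive: int = 6
    require_betweenness_above_mean: bool = True
    require_closeness_above_mean: bool = True
    nonspecific_blocklist: frozenset[str] = DEFAULT_NONSPECIFIC_BLOCKLIST

    def __post_init__(self) -> None:
        if self.min_degree_exclusive < 0:
            raise ValueError("min_degree_exclusive must be >= 0")


@dataclass(frozen=True)
class ScreeningResult:
    """Selected node ids (deterministically ordered) plus a full audit.

    ``audit`` maps every screened-class node to a record of each criterion's
    outcome and the thresholds applied; ``selected`` contains exactly the
    nodes passing all active criteria, ordered by (degree desc, betweenness
    desc, node id asc).
    """

    selected: tuple[str, ...]
    audit: dict[str, dict]
    thresholds: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "audit": {k: dict(v) for k, v in sorted(self.audit.items())},
            "thresholds": dict(self.thresholds),
        }


def _ordered_selection(table: pd.DataFrame, ids: set[str]) -> tuple[str, ...]:
    rows = table.loc[sorted(ids)]
    order = rows.sort_values(
        by=["degree", "betweenness"], ascending=[False, False], kind="stable"
    )
    # stable sort on already-sorted index gives id-ascending tie-break
    return tuple(order.index)


def screen_key_targets(table: pd.DataFrame, criteria: TargetCriteria = TargetCriteria()) -> ScreeningResult:
    """Screen target-class nodes of a CTN centrality table.

    Candidates are the targets whose degree ranks in the top ``top_k_degree``
    by value, with all ties at the boundary value included; the mean
    comparisons are strict and taken over the whole target class.
    """
    targets = table[table["node_class"] == "target"]
    if targets.empty:
        raise ValueError("no target-class nodes in centrality table")
    degrees = sorted(targets["degree"], reverse=True)
    k = min(criteria.top_k_degree, len(degrees))
    boundary = degrees[k - 1]
    mean_bet = class_mean(table, "betweenness", "target")
    mean_clo = class_mean(table, "closeness", "target")

    audit: dict[str, dict] = {}
    selected: set[str] = set()
    for node, row in targets.iterrows():
        in_top_k = row["degree"] >= boundary
        bet_ok = (not criteria.require_betweenness_above_mean) or row["betweenness"] > mean_bet
        clo_ok = (not criteria.require_closeness_above_mean) or row["closeness"] > mean_clo
        ok = bool(in_top_k and bet_ok and clo_ok)
        audit[node] = {
            "degree": int(row["degree"]),
            "in_top_k": bool(in_top_k),
            "betweenness_above_mean": bool(row["betweenness"] > mean_bet),
            "closeness_above_mean": bool(row["closeness"] > mean_clo),
            "selected": ok,
        }
        if ok:
            selected.add(node)
    return ScreeningResult(
        selected=_ordered_selection(table, selected),
        audit=audit,
        thresholds={
            "degree_boundary": float(boundary),
            "mean_betweenness": mean_bet,
            "mean_closeness": mean_clo,
        },
    )


def screen_important_pathways(
    table: pd.DataFrame,
    criteria: PathwayCriteria = PathwayCriteria(),
    pathway_names: Optional[Mapping[str, str]] = None,
) -> ScreeningResult:
    """Cascade screen of pathway-class nodes of a TPN centrality table.

    Stages, in order: degree > cut-off; betweenness > class mean; blocklist
    of non-specific pathways (matched case-insensitively against the node id
    and, when ``pathway_names`` maps ids to display names, the name);
    closeness > class mean. The audit records the stage at which each
    pathway was removed (``None`` if selected).
    """
    pathways = table[table["node_class"] == "pathway"]
    if pathways.empty:
        raise ValueError("no pathway-class nodes in centrality table")
    mean_bet = class_mean(table, "betweenness", "pathway")
    mean_clo = class_mean(table, "closeness", "pathway")
    blocklist = {b.lower() for b in criteria.nonspecific_blocklist}

    audit: dict[str, dict] = {}
    selected: set[str] = set()
    for node, row in pathways.iterrows():
        name = (pathway_names or {}).get(node, "")
        blocked = node.lower() in blocklist or (name and name.lower() in blocklist)
        stage = None
        if not row["degree"] > criteria.min_degree_exclusive:
            stage = "degree"
        elif criteria.require_betweenness_above_mean and not row["betweenness"] > mean_bet:
            stage = "betweenness"
        elif blocked:
            stage = "nonspecific"
        elif criteria.require_closeness_above_mean and not row["closeness"] > mean_clo:
            stage = "closeness"
        audit[node] = {
            "degree": int(row["degree"]),
            "removed_at": stage,
            "selected": stage is None,
        }
        if stage is None:
            selected.add(node)
    return ScreeningResult(
        selected=_ordered_selection(table, selected),
        audit=audit,
        thresholds={
            "min_degree_exclusive": float(criteria.min_degree_exclusive),
            "mean_betweenness": mean_bet,
            "mean_closeness": mean_clo,
        },
    )


# ---------------------------------------------------------------------------
# Pathway cross-talk fixture
# ---------------------------------------------------------------------------

#: The seven signalling pathways of the curated cross-talk map.
CROSSTALK_PATHWAYS = frozenset(
    {
        "estrogen signaling pathway",
        "PI3K-AKT signaling pathway",
        "cGMP-PKG signaling pathway",
        "calcium signaling pathway",
        "cAMP signaling pathway",
        "MAPK signaling pathway",
        "NF-κB signaling pathway",
    }
)

#: Every other pathway feeds into this one.
HUB_PATHWAY = "NF-κB signaling pathway"


@dataclass(frozen=True)
class CrosstalkEdge:
    """A directed regulation between two signalling pathways.

    ``connector`` names the mediating molecule(s); feedback regulations are
    drawn dashed in the original map and flagged here.
    """

    from_pathway: str
    to_pathway: str
    connector: str = ""
    is_feedback: bool = False

    def __post_init__(self) -> None:
        if self.from_pathway == self.to_pathway:
            raise ValueError(f"self cross-talk on {self.from_pathway!r}")
        for p in (self.from_pathway, self.to_pathway):
            if p not in CROSSTALK_PATHWAYS:
                raise ValueError(f"unknown pathway name {p!r}")


def load_crosstalk(path: Union[str, Path], sep: str = ",") -> list[CrosstalkEdge]:
    """Load the curated cross-talk edge table, vocabulary-checked."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    required = {"from_pathway", "to_pathway"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"crosstalk table missing columns: {sorted(missing)}")
    edges = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        edges.append(
            CrosstalkEdge(
                from_pathway=rec["from_pathway"].strip(),
                to_pathway=rec["to_pathway"].strip(),
                connector=rec.get("connector", "").strip(),
                is_feedback=rec.get("is_feedback", "0").strip() in {"1", "true", "True"},
            )
        )
    return edges


def validate_crosstalk(edges: Sequence[CrosstalkEdge]) -> None:
    """Check the map's structural property: every other pathway has at least
    one direct regulation into the hub pathway."""
    into_hub = {e.from_pathway for e in edges if e.to_pathway == HUB_PATHWAY}
    missing = CROSSTALK_PATHWAYS - {HUB_PATHWAY} - into_hub
    if missing:
        raise ValueError(
            f"pathway(s) with no edge into {HUB_PATHWAY!r}: {sorted(missing)}"
        )
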