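"""One-shot orchestration of the full inference chain.

Reads a YAML/dict config naming the input tables, then runs: docking filter
-> multi-source integration -> CTN build -> centrality -> key-target screen
-> (if pathway memberships given) TPN build -> centrality -> pathway screen
-> CTPN build, and returns a machine-readable report. Every threshold is a
config key with the conventional value as default. Missing optional inputs
skip the affected stages with a log line rather than failing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from . import __version__
from .build import NetworkSummary, build_ctn, build_ctpn, build_tpn, summarize
from .centrality import centrality_table
from .dock import IntegrationReport, ThresholdSpec, filter_docking, integrate_targets
from .io import (
    read_compound_table,
    read_docking_table,
    read_interaction_edges,
    read_pathway_memberships,
)
from .screening import (
    PathwayCriteria,
    ScreeningResult,
    TargetCriteria,
    screen_important_pathways,
    screen_key_targets,
    DEFAULT_NONSPECIFIC_BLOCKLIST,
)

__all__ = ["RunReport", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("netpharm.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "inputs": {
        "compounds": None,
        "docking": None,
        "known_edges": None,
        "target_pathways": None,
    },
    "ki_molar": 1e-6,
    "temperature_k": 298.15,
    "pinned_energy": None,
    "inclusive_threshold": False,
    "top_k_degree": 10,
    "pathway_min_degree": 6,
    "blocklist": sorted(DEFAULT_NONSPECIFIC_BLOCKLIST),
    "selected_pathways": None,
}


@dataclass(frozen=True)
class RunReport:
    """Everything one run computed, serializable without loss."""

    threshold_energy: float
    integration: Optional[IntegrationReport]
    ctn_summary: Optional[NetworkSummary]
    tpn_summary: Optional[NetworkSummary]
    ctpn_summary: Optional[NetworkSummary]
    key_targets: Optional[ScreeningResult]
    important_pathways: Optional[ScreeningResult]
    config: dict[str, Any]
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        def opt(x, f):
            return f(x) if x is not None else None

        return {
            "threshold_energy": self.threshold_energy,
            "integration": opt(self.integration, lambda r: vars(r).copy()),
            "ctn_summary": opt(self.ctn_summary, lambda s: s.to_dict()),
            "tpn_summary": opt(self.tpn_summary, lambda s: s.to_dict()),
            "ctpn_summary": opt(self.ctpn_summary, lambda s: s.to_dict()),
            "key_targets": opt(self.key_targets, lambda r: r.to_dict()),
            "important_pathways": opt(self.important_pathways, lambda r: r.to_dict()),
            "config": self.config,
            "version": self.version,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, ensure_ascii=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunReport":
        def opt(x, f):
            return f(x) if x is not None else None

        return cls(
            threshold_energy=d["threshold_energy"],
            integration=opt(d["integration"], lambda r: IntegrationReport(**r)),
            ctn_summary=opt(d["ctn_summary"], lambda s: NetworkSummary(**s)),
            tpn_summary=opt(d["tpn_summary"], lambda s: NetworkSummary(**s)),
            ctpn_summary=opt(d["ctpn_summary"], lambda s: NetworkSummary(**s)),
            key_targets=opt(d["key_targets"], _screening_from_dict),
            important_pathways=opt(d["important_pathways"], _screening_from_dict),
            config=d["config"],
            version=d.get("version", __version__),
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))


def _screening_from_dict(d: dict[str, Any]) -> ScreeningResult:
    return ScreeningResult(
        selected=tuple(d["selected"]),
        audit=d["audit"],
        thresholds=d["thresholds"],
    )


def _load_config(config: Union[str, Path, dict[str, Any]]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    merged = {**DEFAULT_CONFIG, **config}
    merged["inputs"] = {**DEFAULT_CONFIG["inputs"], **(config.get("inputs") or {})}
    unknown = set(merged) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return merged


def run_pipeline(config: Union[str, Path, dict[str, Any]]) -> RunReport:
    """Execute the chain described by ``config`` and return a RunReport."""
    cfg = _load_config(config)
    inputs = cfg["inputs"]

    spec = ThresholdSpec(
        ki_molar=float(cfg["ki_molar"]),
        temperature_k=float(cfg["temperature_k"]),
        pinned_energy=cfg["pinned_energy"],
    )
    threshold = spec.derived_energy
    log.info("[threshold] applying binding-energy cut-off %.4f kcal/mol "
             "(Ki=%g M, T=%g K)", threshold, spec.ki_molar, spec.temperature_k)

    if inputs.get("compounds"):
        compounds = read_compound_table(inputs["compounds"])
        log.info("[compounds] %d compounds read", len(compounds))

    docked = []
    if inputs.get("docking"):
        records = read_docking_table(inputs["docking"])
        docked = filter_docking(records, spec, inclusive=bool(cfg["inclusive_threshold"]))
        log.info("[dock] %d/%d docking records pass", len(docked), len(records))
    else:
        log.info("[dock] no docking table; stage skipped")

    known = []
    if inputs.get("known_edges"):
        known = read_interaction_edges(inputs["known_edges"])
        log.info("[known] %d known edges read", len(known))
    else:
        log.info("[known] no known-edge table; stage skipped")

    edges, integration = integrate_targets(known, docked)
    log.info("[integrate] %d unique targets after deduplication", integration.n_union)
    if not edges:
        raise ValueError("no compound-target edges: provide docking and/or known_edges")

    ctn = build_ctn(edges)
    ctn_summary = summarize(ctn)
    ctn_table = centrality_table(ctn)
    key_targets = screen_key_targets(ctn_table, TargetCriteria(top_k_degree=int(cfg["top_k_degree"])))
    log.info("[ctn] %d nodes / %d edges; %d key targets",
             ctn_summary.n_nodes, ctn_summary.n_edges, len(key_targets.selected))

    tpn_summary = ctpn_summary = important = None
    if inputs.get("target_pathways"):
        members = read_pathway_memberships(inputs["target_pathways"])
        tpn = build_tpn(members, set(ctn.nodes("target")))
        tpn_summary = summarize(tpn)
        names = {m.pathway_id: m.pathway_name for m in members if m.pathway_name}
        if tpn.nodes("pathway"):
            tpn_table = centrality_table(tpn)
            important = screen_important_pathways(
                tpn_table,
                PathwayCriteria(
                    min_degree_exclusive=int(cfg["pathway_min_degree"]),
                    nonspecific_blocklist=frozenset(cfg["blocklist"]),
                ),
                pathway_names=names,
            )
            selected = cfg["selected_pathways"]
            if selected is None:
                selected = list(important.selected)
            ctpn = build_ctpn(ctn, tpn, selected)
            ctpn_summary = summarize(ctpn)
            log.info("[tpn] %d nodes / %d edges; %d important pathways; CTPN %d/%d",
                     tpn_summary.n_nodes, tpn_summary.n_edges,
                     len(important.selected), ctpn_summary.n_nodes, ctpn_summary.n_edges)
        else:
            log.info("[tpn] no pathway links survive the whitelist; screening skipped")
    else:
        log.info("[tpn] no pathway membership table; stage skipped")

    return RunReport(
        threshold_energy=threshold,
        integration=integration,
        ctn_summary=ctn_summary,
        tpn_summary=tpn_summary,
        ctpn_summary=ctpn_summary,
        key_targets=key_targets,
        important_pathways=important,
        config=cfg,
    )
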