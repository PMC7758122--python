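"""Seeded generator of synthetic tripartite compound-target-pathway data.

The generator emulates the statistical shape of a small multi-herb
preparation screened against a protein panel: a dozen compounds, a few dozen
targets of which a handful are planted hubs with inflated degree, pathway
membership lists whose sizes follow a Dirichlet-multinomial (a few large
pathways, many small ones), and docking energies drawn from a two-component
Gaussian mixture of strong binders and non-binders straddling the 1 uM
threshold near -8.18 kcal/mol.

Every draw flows from one ``numpy`` generator seeded once, and the returned
ledger records the planted structure (hub ids, per-pathway sizes, exact edge
counts) so downstream network summaries can be checked against it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import Compound, DockingRecord, InteractionEdge, PathwayMembership

__all__ = ["GeneratorConfig", "generate_tripartite", "generate_docking_table"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic tripartite generator.

    Defaults mirror the scale of the packaged study fixtures: 13 compounds,
    84 targets with 12 hubs, ~200 pathways, a compound-target background
    density giving ~140 edges, and ~580 pathway memberships.
    """

    n_compounds: int = 13
    n_targets: int = 84
    n_pathways: int = 201
    edge_prob_ct: float = 0.084
    hub_targets: int = 12
    hub_boost: float = 5.0
    membership_concentration: float = 0.3
    memberships_per_target: float = 6.9
    active_energy_mean: float = -9.5
    active_energy_sd: float = 0.8
    inactive_energy_mean: float = -6.8
    inactive_energy_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_prob_ct <= 1.0:
            raise ValueError("edge_prob_ct must be in [0, 1]")
        if self.active_energy_sd <= 0 or self.inactive_energy_sd <= 0:
            raise ValueError("energy standard deviations must be > 0")
        if min(self.n_compounds, self.n_targets, self.n_pathways, self.hub_targets) < 0:
            raise ValueError("counts must be >= 0")
        if self.hub_boost < 1.0:
            raise ValueError("hub_boost must be >= 1")
        if self.membership_concentration <= 0:
            raise ValueError("membership_concentration must be > 0")
        if self.hub_targets > self.n_targets:
            raise ValueError(
                f"hub_targets ({self.hub_targets}) exceeds n_targets ({self.n_targets})"
            )

    def compound_ids(self) -> list[str]:
        return [f"C{i:02d}" for i in range(1, self.n_compounds + 1)]

    def target_ids(self) -> list[str]:
        # synthetic accessions follow the UniProt grammar
        return [f"P{i:05d}" for i in range(1, self.n_targets + 1)]

    def pathway_ids(self) -> list[str]:
        return [f"hsa{90000 + i:05d}" for i in range(1, self.n_pathways + 1)]


def generate_tripartite(
    config: GeneratorConfig,
) -> tuple[list[Compound], list[InteractionEdge], list[PathwayMembership], dict]:
    """Generate compounds, compound-target edges and pathway memberships.

    Returns ``(compounds, edges, memberships, ledger)``; the ledger holds
    the planted hub accessions, per-pathway membership sizes and exact edge
    counts. Byte-identical across runs for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    compounds_ids = config.compound_ids()
    targets = config.target_ids()
    pathways = config.pathway_ids()

    compounds = [
        Compound(
            abbrev=cid,
            name=f"synthetic compound {cid}",
            mw=float(np.round(rng.uniform(150.0, 550.0), 2)),
            content_mg_per_ml=float(np.round(rng.uniform(0.05, 10.0), 2)),
        )
        for cid in compounds_ids
    ]

    hub_idx = (
        sorted(rng.choice(config.n_targets, size=config.hub_targets, replace=False).tolist())
        if config.hub_targets
        else []
    )
    hub_set = set(hub_idx)
    probs = np.full(config.n_targets, config.edge_prob_ct)
    for i in hub_idx:
        probs[i] = min(1.0, config.edge_prob_ct * config.hub_boost)

    edges: list[InteractionEdge] = []
    for cid in compounds_ids:
        hits = rng.random(config.n_targets) < probs
        for j in np.nonzero(hits)[0]:
            edges.append(
                InteractionEdge(
                    compound_abbrev=cid,
                    uniprot_ac=targets[j],
                    evidence="database",
                    source_label="synthetic",
                )
            )

    memberships: list[PathwayMembership] = []
    pathway_sizes: dict[str, int] = {}
    if config.n_pathways and config.n_targets:
        weights = rng.dirichlet(
            np.full(config.n_pathways, config.membership_concentration)
        )
        total = int(round(config.memberships_per_target * config.n_targets))
        counts = rng.multinomial(total, weights)
        for pid, count in zip(pathways, counts):
            size = int(min(count, config.n_targets))
            pathway_sizes[pid] = size
            if size == 0:
                continue
            chosen = rng.choice(config.n_targets, size=size, replace=False)
            for j in sorted(chosen.tolist()):
                memberships.append(
                    PathwayMembership(
                        uniprot_ac=targets[j],
                        pathway_id=pid,
                        pathway_name=f"synthetic pathway {pid}",
                    )
                )

    ledger = {
        "config": asdict(config),
        "hub_targets": [targets[i] for i in hub_idx],
        "n_ct_edges": len(edges),
        "compounds_with_edges": sorted({e.compound_abbrev for e in edges}),
        "targets_with_edges": sorted({e.uniprot_ac for e in edges}),
        "pathway_sizes": pathway_sizes,
        "n_memberships": len(memberships),
        "targets_with_pathways": sorted({m.uniprot_ac for m in memberships}),
    }
    return compounds, edges, memberships, ledger


def generate_docking_table(
    config: GeneratorConfig,
    true_binders: Iterable[tuple[str, str]],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> list[DockingRecord]:
    """Docking energies for compound-target pairs, seeded.

    ``pairs`` defaults to the full compound x target cross product of the
    config; pairs in ``true_binders`` draw from the active (strong-binder)
    Gaussian, the rest from the inactive one.
    """
    rng = np.random.default_rng(config.seed + 1)
    binders = set(true_binders)
    if pairs is None:
        pairs = [
            (c, t) for c in config.compound_ids() for t in config.target_ids()
        ]
    records = []
    for c, t in pairs:
        if (c, t) in binders:
            energy = rng.normal(config.active_energy_mean, config.active_energy_sd)
        else:
            energy = rng.normal(config.inactive_energy_mean, config.inactive_energy_sd)
        records.append(
            DockingRecord(
                compound_abbrev=c,
                target_name=f"synthetic protein {t}",
                uniprot_ac=t,
                binding_energy=float(energy),
            )
        )
    return records
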