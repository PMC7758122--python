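"""Docking-score screening: Ki <-> binding free energy, threshold filtering,
and multi-source target integration.

The thermodynamic link is the standard relation dG = RT ln(Ki): a ligand
with inhibition constant 1 uM at room temperature corresponds to a binding
free energy near -8.18 kcal/mol, the customary cut-off for calling a docked
protein a target of the compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import DockingRecord, InteractionEdge

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "ki_to_binding_energy",
    "binding_energy_to_ki",
    "ThresholdSpec",
    "IntegrationReport",
    "filter_docking",
    "integrate_targets",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204e-3

#: Standard-state temperature (K) used when none is given.
STANDARD_TEMPERATURE_K = 298.15


def ki_to_binding_energy(ki_molar: float, temperature_k: float = STANDARD_TEMPERATURE_K) -> float:
    """Binding free energy (kcal/mol) equivalent to an inhibition constant.

    dG = R T ln(Ki) with Ki in mol/L; Ki < 1 M gives a negative energy.
    """
    if not ki_molar > 0:
        raise ValueError(f"ki_molar must be > 0, got {ki_molar}")
    if not temperature_k > 0:
        raise ValueError(f"temperature_k must be > 0, got {temperature_k}")
    return GAS_CONSTANT_KCAL * temperature_k * math.log(ki_molar)


def binding_energy_to_ki(energy: float, temperature_k: float = STANDARD_TEMPERATURE_K) -> float:
    """Inverse of :func:`ki_to_binding_energy`: Ki (mol/L) from dG (kcal/mol)."""
    if not temperature_k > 0:
        raise ValueError(f"temperature_k must be > 0, got {temperature_k}")
    return math.exp(energy / (GAS_CONSTANT_KCAL * temperature_k))


@dataclass(frozen=True)
class ThresholdSpec:
    """Docking acceptance threshold expressed as an inhibition constant.

    The energy cut-off is recomputed from ``ki_molar`` at ``temperature_k``
    so its thermodynamic provenance stays explicit; ``pinned_energy`` lets a
    literal published cut-off (e.g. -8.18 kcal/mol) override the derived one.
    """

    ki_molar: float = 1e-6
    temperature_k: float = STANDARD_TEMPERATURE_K
    pinned_energy: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ki_molar > 0:
            raise ValueError(f"ki_molar must be > 0, got {self.ki_molar}")
        if not self.temperature_k > 0:
            raise ValueError(f"temperature_k must be > 0, got {self.temperature_k}")

    @property
    def derived_energy(self) -> float:
        """The energy cut-off in kcal/mol actually applied."""
        if self.pinned_energy is not None:
            return self.pinned_energy
        return ki_to_binding_energy(self.ki_molar, self.temperature_k)


@dataclass(frozen=True)
class IntegrationReport:
    """Target-level bookkeeping of multi-source integration.

    Counts are over unique protein accessions, not edges, and satisfy
    inclusion-exclusion: ``n_union = n_known + n_docking - n_overlap``.
    """

    n_known: int
    n_docking: int
    n_union: int
    n_overlap: int

    def __post_init__(self) -> None:
        if min(self.n_known, self.n_docking, self.n_union, self.n_overlap) < 0:
            raise ValueError("all counts must be non-negative")
        if self.n_union != self.n_known + self.n_docking - self.n_overlap:
            raise ValueError("inclusion-exclusion identity violated")


def filter_docking(
    records: Sequence[DockingRecord],
    spec: ThresholdSpec = ThresholdSpec(),
    inclusive: bool = False,
) -> list[InteractionEdge]:
    """Keep records whose binding energy beats the threshold.

    "Lower than" is strict by default (more negative passes); ``inclusive``
    switches to <= for ties at exactly the cut-off. Input order is preserved.
    """
    cutoff = spec.derived_energy
    passed = []
    for r in records:
        ok = r.binding_energy <= cutoff if inclusive else r.binding_energy < cutoff
        if ok:
            passed.append(
                InteractionEdge(
                    compound_abbrev=r.compound_abbrev,
                    uniprot_ac=r.uniprot_ac,
                    evidence="docking",
                    source_label="docking",
                )
            )
    return passed


def integrate_targets(
    known: Iterable[InteractionEdge],
    docked: Iterable[InteractionEdge],
) -> tuple[list[InteractionEdge], IntegrationReport]:
    """Union two edge lists, deduplicated on (compound, target).

    A pair evidenced both ways keeps a single edge recorded as database
    evidence with the source labels concatenated. The report counts unique
    target accessions per evidence kind.
    """
    known = list(known)
    docked = list(docked)
    merged: dict[tuple[str, str], InteractionEdge] = {}
    for e in known:
        if e.pair in merged:
            raise ValueError(f"known edges not deduplicated: {e.pair}")
        merged[e.pair] = e
    for e in docked:
        prev = merged.get(e.pair)
        if prev is None:
            merged[e.pair] = e
        elif prev.evidence == "docking":
            raise ValueError(f"docked edges not deduplicated: {e.pair}")
        else:
            labels = [s for s in (prev.source_label, e.source_label) if s]
            merged[e.pair] = InteractionEdge(
                compound_abbrev=e.compound_abbrev,
                uniprot_ac=e.uniprot_ac,
                evidence="database",
                source_label="+".join(labels),
            )
    known_targets = {e.uniprot_ac for e in known}
    docked_targets = {e.uniprot_ac for e in docked}
    report = IntegrationReport(
        n_known=len(known_targets),
        n_docking=len(docked_targets),
        n_union=len(known_targets | docked_targets),
        n_overlap=len(known_targets & docked_targets),
    )
    return list(merged.values()), report
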