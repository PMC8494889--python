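"""Cytotoxicity assessment from resazurin signals and live/dead counts.

Two orthogonal viability readouts are combined: a bulk metabolic
resazurin assay (treated signal over vehicle-control signal) and a
high-content live/dead cell count per well. Each compound's readouts
across a concentration series form a :class:`DoseResponseProfile`; a
compound is called toxic when *either* assay drops below the viability
threshold (default 0.70) at any concentration at or below the screening
concentration. Concentrations above the screening dose are ignored —
toxicity there cannot confound the screen readout.

No dose–response curve is fitted; the verdict is rule-based on the
measured points.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "ViabilityAssay",
    "DoseResponseProfile",
    "ToxicityCall",
    "ViabilityError",
    "resazurin_viability",
    "hcs_viability",
    "classify_toxicity",
    "DEFAULT_VIABILITY_THRESHOLD",
]

#: Conventional cytotoxicity bound (70% viability).
DEFAULT_VIABILITY_THRESHOLD = 0.70


class ViabilityError(ValueError):
    """Degenerate or incomplete viability input."""


class ViabilityAssay(str, enum.Enum):
    RESAZURIN = "resazurin"
    HCS_COUNT = "hcs_count"


@dataclass(frozen=True)
class DoseResponseProfile:
    """Viability fraction over a strictly increasing concentration series."""

    compound_id: str
    assay: ViabilityAssay
    points: tuple[tuple[float, float], ...]  # (concentration_uM, viability)

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ViabilityError(
                f"{self.compound_id}/{self.assay.value}: concentrations must be "
                f"strictly increasing, got {concs}"
            )
        for c, v in self.points:
            if not (0.0 <= v <= 1.0):
                raise ViabilityError(
                    f"{self.compound_id}/{self.assay.value}: viability {v} at "
                    f"{c} uM outside [0, 1] (clamp raw assay values first)"
                )

    def viabilities_at_or_below(self, concentration_uM: float) -> list[tuple[float, float]]:
        return [(c, v) for c, v in self.points if c <= concentration_uM]


@dataclass(frozen=True)
class ToxicityCall:
    compound_id: str
    toxic: bool
    min_toxic_concentration: float | None
    threshold: float
    assay_concentration: float


def _clamp_viability(value: float, label: str) -> float:
    if value > 1.0:
        # routine for healthy wells under multiplicative noise
        logger.debug("%s: viability %.3f > 1 clamped to 1.0 (assay noise)", label, value)
        return 1.0
    if value < 0.0:
        logger.warning("%s: viability %.3f < 0 clamped to 0.0", label, value)
        return 0.0
    return value


def resazurin_viability(
    treated_signals: list[float],
    vehicle_control_signals: list[float],
    label: str = "resazurin",
) -> float:
    """mean(treated) ÷ mean(vehicle controls), clamped to [0, 1]."""
    if len(treated_signals) < 1:
        raise ViabilityError(f"{label}: need >= 1 treated signal")
    if len(vehicle_control_signals) < 3:
        raise ViabilityError(
            f"{label}: need >= 3 vehicle-control signals, got {len(vehicle_control_signals)}"
        )
    control_mean = sum(vehicle_control_signals) / len(vehicle_control_signals)
    if control_mean <= 0:
        raise ViabilityError(f"{label}: control mean {control_mean} is degenerate")
    treated_mean = sum(treated_signals) / len(treated_signals)
    return _clamp_viability(treated_mean / control_mean, label)


def hcs_viability(live_count: int, dead_count: int) -> float:
    """live ÷ (live + dead) for one imaged well."""
    if live_count < 0 or dead_count < 0:
        raise ViabilityError("cell counts must be non-negative")
    total = live_count + dead_count
    if total == 0:
        raise ViabilityError("no cells counted in well; viability undefined")
    return live_count / total


def classify_toxicity(
    profiles: list[DoseResponseProfile],
    assay_concentration: float,
    threshold: float = DEFAULT_VIABILITY_THRESHOLD,
) -> ToxicityCall:
    """OR-combine assays: toxic iff any assay dips below threshold at a
    tested concentration ≤ the screening concentration."""
    if not profiles:
        raise ViabilityError("at least one dose-response profile is required")
    compound_id = profiles[0].compound_id
    if any(p.compound_id != compound_id for p in profiles):
        raise ViabilityError("all profiles must belong to the same compound")

    offending: list[float] = []
    covered = False
    for profile in profiles:
        points = profile.viabilities_at_or_below(assay_concentration)
        if points:
            covered = True
        offending.extend(c for c, v in points if v < threshold)
    if not covered:
        raise ViabilityError(
            f"{compound_id}: no tested concentration <= assay concentration "
            f"{assay_concentration} uM; cannot judge toxicity"
        )
    toxic = bool(offending)
    return ToxicityCall(
        compound_id=compound_id,
        toxic=toxic,
        min_toxic_concentration=min(offending) if toxic else None,
        threshold=threshold,
        assay_concentration=assay_concentration,
    )
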