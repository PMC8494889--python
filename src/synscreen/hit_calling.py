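"""Fold-change normalization and control-SD hit calling.

Each compound well is normalized to the mean untreated-control signal of
its own plate, which removes multiplicative plate-to-plate factors
(reader gain, cell seeding density). Hit thresholds are derived from the
spread of the control wells themselves: the pooled sample SD of
untreated-control fold changes across all plates, multiplied by ``k``
(default 4), gives a symmetric band around 1. Compounds whose consensus
fold change lies strictly outside the band are called activators
(above) or inhibitors (below); everything inside is inactive.

With the control fold-change SD at 0.0825 the default band is
1 ± 0.33, i.e. (0.67, 1.33).
"""

from __future__ import annotations

import enum
import logging
import math
import statistics
from dataclasses import dataclass, field

from .plate_model import Plate, ScreenRun, Well, WellType

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeRecord",
    "HitThreshold",
    "HitCall",
    "HitClass",
    "ConsensusRule",
    "NormalizationError",
    "normalize_plate",
    "normalize_run",
    "estimate_control_sd",
    "call_hits",
]


class NormalizationError(ValueError):
    """Plate cannot be normalized (too few controls, degenerate mean)."""


class HitClass(str, enum.Enum):
    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"
    INACTIVE = "inactive"


class ConsensusRule(str, enum.Enum):
    """How per-replicate fold changes combine into one verdict.

    ``MEAN``: classify the mean fold change (default). ``MAJORITY``:
    classify each replicate, take the most frequent class (ties ->
    inactive). ``ALL``: a compound is a hit only when every replicate
    agrees on the same non-inactive class.
    """

    MEAN = "mean"
    MAJORITY = "majority"
    ALL = "all"


@dataclass(frozen=True)
class FoldChangeRecord:
    """Control-normalized signal of one well in one replicate.

    Control wells get records too (``compound_id`` None) — their spread
    is what calibrates the hit threshold.
    """

    compound_id: str | None
    replicate_index: int
    plate_id: str
    fold_change: float
    well_type: WellType = WellType.COMPOUND

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(
                f"fold change must be > 0, got {self.fold_change} "
                f"({self.plate_id}/{self.compound_id})"
            )


@dataclass(frozen=True)
class HitThreshold:
    """Symmetric hit band 1 ± k·SD on the linear fold-change scale."""

    control_sd: float
    k: float = 4.0

    def __post_init__(self) -> None:
        if self.control_sd < 0:
            raise ValueError("control_sd must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.lower_bound <= 0:
            raise ValueError(
                f"lower bound 1 - k*sd = {self.lower_bound:.4f} is not positive; "
                "the additive band is meaningless for this SD/k"
            )
        if self.control_sd == 0:
            logger.warning(
                "degenerate threshold: control SD is 0, band collapses to (1, 1) "
                "and every non-unit fold change is a hit"
            )

    @property
    def offset(self) -> float:
        return self.k * self.control_sd

    @property
    def lower_bound(self) -> float:
        return 1.0 - self.offset

    @property
    def upper_bound(self) -> float:
        return 1.0 + self.offset

    def classify(self, fold_change: float) -> HitClass:
        """Strictly-beyond rule: boundary values are inactive."""
        if fold_change > self.upper_bound:
            return HitClass.ACTIVATOR
        if fold_change < self.lower_bound:
            return HitClass.INHIBITOR
        return HitClass.INACTIVE


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    mean_fold_change: float
    classification: HitClass
    n_replicates_used: int
    fold_changes: tuple[float, ...] = field(default=())

    @property
    def potency(self) -> float:
        """Distance of the consensus fold change from 1 (ranking utility)."""
        return abs(self.mean_fold_change - 1.0)


def _control_mean(plate: Plate, control_type: WellType) -> float:
    plate.require_controls(control_type)
    values = [w.signal for w in plate.wells_of_type(control_type) if not w.missing]
    mean = sum(values) / len(values)
    if mean <= 0:
        raise NormalizationError(
            f"plate {plate.plate_id}: {control_type.value} mean signal is "
            f"{mean}; cannot normalize a degenerate plate"
        )
    return mean


def normalize_plate(
    plate: Plate,
    control_type: WellType = WellType.UNTREATED_CONTROL,
) -> list[FoldChangeRecord]:
    """Per-plate fold changes: signal ÷ mean control signal of this plate.

    Returns records for compound wells *and* for the normalizing control
    wells (whose per-plate mean fold change is exactly 1 — that is what
    makes their pooled SD a valid null-spread estimate). Wells with
    missing signals are skipped with a log note.
    """
    mean = _control_mean(plate, control_type)
    records: list[FoldChangeRecord] = []
    skipped = 0
    for well in plate.wells:
        if well.well_type not in (WellType.COMPOUND, control_type):
            continue
        if well.missing:
            skipped += 1
            continue
        if well.well_type is WellType.COMPOUND and well.signal == 0:
            skipped += 1
            logger.warning(
                "plate %s well %s: zero signal, fold change undefined; skipped",
                plate.plate_id,
                well.address,
            )
            continue
        if well.well_type is control_type and well.signal == 0:
            skipped += 1
            continue
        records.append(
            FoldChangeRecord(
                compound_id=well.compound_id,
                replicate_index=plate.replicate_index,
                plate_id=plate.plate_id,
                fold_change=well.signal / mean,
                well_type=well.well_type,
            )
        )
    if skipped:
        logger.info("plate %s: %d well(s) excluded from normalization", plate.plate_id, skipped)
    return records


def normalize_run(
    run: ScreenRun,
    control_type: WellType = WellType.UNTREATED_CONTROL,
) -> list[FoldChangeRecord]:
    """Normalize every plate of a run."""
    records: list[FoldChangeRecord] = []
    for plate in run.plates:
        records.extend(normalize_plate(plate, control_type))
    return records


def estimate_control_sd(
    source: ScreenRun | list[FoldChangeRecord],
    k: float = 4.0,
    control_type: WellType = WellType.UNTREATED_CONTROL,
) -> HitThreshold:
    """Pooled sample SD (n−1) of control fold changes across all plates.

    One global SD — hence one global cutoff — is estimated for the whole
    run, matching the single printed screen-wide band.
    """
    if isinstance(source, ScreenRun):
        records = normalize_run(source, control_type)
    else:
        records = source
    values = [r.fold_change for r in records if r.well_type is control_type]
    if len(values) < 2:
        raise NormalizationError(
            f"need >= 2 {control_type.value} fold changes to estimate the "
            f"threshold SD, got {len(values)}"
        )
    return HitThreshold(control_sd=statistics.stdev(values), k=k)


def _consensus_class(
    fold_changes: list[float],
    threshold: HitThreshold,
    rule: ConsensusRule,
) -> HitClass:
    mean_fc = sum(fold_changes) / len(fold_changes)
    if rule is ConsensusRule.MEAN:
        return threshold.classify(mean_fc)
    per_rep = [threshold.classify(fc) for fc in fold_changes]
    if rule is ConsensusRule.ALL:
        first = per_rep[0]
        if first is not HitClass.INACTIVE and all(c is first for c in per_rep):
            return first
        return HitClass.INACTIVE
    # MAJORITY: most frequent class; ties resolve to inactive
    counts = {c: per_rep.count(c) for c in HitClass}
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else HitClass.INACTIVE


def call_hits(
    records: list[FoldChangeRecord],
    threshold: HitThreshold,
    consensus: ConsensusRule | str = ConsensusRule.MEAN,
) -> list[HitCall]:
    """One consensus :class:`HitCall` per compound.

    Classification partitions the compound set: every compound is
    exactly one of activator / inhibitor / inactive. Compounds with no
    usable records are skipped with a warning.
    """
    rule = ConsensusRule(consensus)
    by_compound: dict[str, list[FoldChangeRecord]] = {}
    for rec in records:
        if rec.well_type is WellType.COMPOUND and rec.compound_id:
            by_compound.setdefault(rec.compound_id, []).append(rec)

    calls: list[HitCall] = []
    for cid, recs in by_compound.items():
        fcs = [r.fold_change for r in sorted(recs, key=lambda r: r.replicate_index)]
        if not fcs:
            logger.warning("compound %s has no usable fold changes; skipped", cid)
            continue
        mean_fc = sum(fcs) / len(fcs)
        calls.append(
            HitCall(
                compound_id=cid,
                mean_fold_change=mean_fc,
                classification=_consensus_class(fcs, threshold, rule),
                n_replicates_used=len(fcs),
                fold_changes=tuple(fcs),
            )
        )
    return calls


def rank_by_potency(calls: list[HitCall]) -> list[HitCall]:
    """Sort hits by |mean fold change − 1|, strongest first.

    Utility for picking the "most potent" subset for follow-up assays;
    the ranking criterion is a package convention, not a measured fact.
    """
    return sorted(calls, key=lambda c: (-c.potency, c.compound_id))


__all__.append("rank_by_potency")
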