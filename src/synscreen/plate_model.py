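"""Domain model for microtiter screening plates.

Wells, plates and screen runs are the common currency of every analysis
step: a :class:`Well` is one measured position with its role (compound,
untreated control, vehicle/DMSO control, positive control or empty), a
:class:`Plate` is a validated collection of wells in a 384- or 96-well
geometry, and a :class:`ScreenRun` groups the replicate plates of one
screening campaign together with the compound catalog.

The on-disk representation is a long-format UTF-8 CSV with one row per
well and the mandatory header::

    plate_id,replicate,row,col,well_type,compound_id,concentration_uM,signal

Lines starting with ``#`` are treated as comments (the synthetic-data
generator records its seed there). Missing signals are retained as NaN
and flagged, never silently dropped.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WellType",
    "PlateGeometry",
    "Well",
    "Plate",
    "ScreenRun",
    "PlateFormatError",
    "PlateValidationError",
    "read_plate_table",
    "write_plate_table",
    "control_wells",
    "check_randomization",
    "PLATE_TABLE_COLUMNS",
]

PLATE_TABLE_COLUMNS = [
    "plate_id",
    "replicate",
    "row",
    "col",
    "well_type",
    "compound_id",
    "concentration_uM",
    "signal",
]

#: Minimum number of untreated-control wells a plate must carry before
#: per-plate normalization is allowed.
MIN_CONTROL_WELLS = 3


class PlateFormatError(ValueError):
    """The input table does not conform to the plate CSV dialect."""


class PlateValidationError(ValueError):
    """The table parsed, but violates a plate-model invariant."""


class WellType(str, enum.Enum):
    COMPOUND = "compound"
    UNTREATED_CONTROL = "untreated_control"
    VEHICLE_CONTROL = "vehicle_control"
    POSITIVE_CONTROL = "positive_control"
    EMPTY = "empty"


class PlateGeometry(enum.Enum):
    """Plate format; value is (n_rows, n_cols)."""

    W384 = (16, 24)
    W96 = (8, 12)

    @property
    def n_rows(self) -> int:
        return self.value[0]

    @property
    def n_cols(self) -> int:
        return self.value[1]

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def rows(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_rows)]


_CONTROL_TYPES = frozenset(
    {WellType.UNTREATED_CONTROL, WellType.VEHICLE_CONTROL, WellType.POSITIVE_CONTROL}
)


@dataclass(frozen=True)
class Well:
    """One measured well.

    ``signal`` may be NaN for a dropped/unreadable well; such wells are
    kept (with :attr:`missing` True) but excluded from statistics.
    """

    plate_id: str
    row: str
    col: int
    well_type: WellType
    compound_id: str | None = None
    concentration_uM: float | None = None
    signal: float = math.nan

    def __post_init__(self) -> None:
        if self.well_type is WellType.COMPOUND:
            if not self.compound_id:
                raise PlateValidationError(
                    f"compound well {self.plate_id}/{self.address} lacks a compound_id"
                )
            if self.concentration_uM is None or self.concentration_uM < 0:
                raise PlateValidationError(
                    f"compound well {self.plate_id}/{self.address} needs a "
                    f"concentration_uM >= 0 (got {self.concentration_uM!r})"
                )
        elif self.well_type in _CONTROL_TYPES or self.well_type is WellType.EMPTY:
            if self.compound_id:
                raise PlateValidationError(
                    f"{self.well_type.value} well {self.plate_id}/{self.address} "
                    f"must not carry a compound_id (got {self.compound_id!r})"
                )
        if not math.isnan(self.signal) and self.signal < 0:
            raise PlateValidationError(
                f"negative signal {self.signal} at {self.plate_id}/{self.address}"
            )

    @property
    def address(self) -> str:
        """Standard microtiter address, e.g. ``A01``."""
        return f"{self.row}{self.col:02d}"

    @property
    def missing(self) -> bool:
        return math.isnan(self.signal)


@dataclass
class Plate:
    """A validated collection of wells on one physical plate."""

    plate_id: str
    geometry: PlateGeometry
    replicate_index: int
    wells: list[Well] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise PlateValidationError(
                f"plate {self.plate_id}: replicate_index must be >= 1"
            )
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        valid_rows = set(self.geometry.rows)
        for w in self.wells:
            if w.row not in valid_rows or not (1 <= w.col <= self.geometry.n_cols):
                raise PlateValidationError(
                    f"well address {w.address} outside {self.geometry.name} "
                    f"geometry on plate {self.plate_id}"
                )
            key = (w.row, w.col)
            if key in seen:
                raise PlateValidationError(
                    f"duplicate well address {self.plate_id}/{w.address}"
                )
            seen.add(key)
        if len(self.wells) > self.geometry.capacity:
            raise PlateValidationError(
                f"plate {self.plate_id} holds {len(self.wells)} wells, more than "
                f"the {self.geometry.capacity}-well capacity of {self.geometry.name}"
            )

    def wells_of_type(self, kind: WellType) -> list[Well]:
        return [w for w in self.wells if w.well_type is kind]

    def require_controls(self, kind: WellType = WellType.UNTREATED_CONTROL) -> None:
        """Enforce the minimum-control rule used before normalization."""
        usable = [w for w in self.wells_of_type(kind) if not w.missing]
        if len(usable) < MIN_CONTROL_WELLS:
            raise PlateValidationError(
                f"plate {self.plate_id} has {len(usable)} usable {kind.value} "
                f"wells; >= {MIN_CONTROL_WELLS} are required for normalization"
            )

    @property
    def n_missing(self) -> int:
        return sum(w.missing for w in self.wells)


@dataclass
class ScreenRun:
    """All plates of one screen plus the compound catalog."""

    plates: list[Plate]
    n_replicates: int = 3
    compound_catalog: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for plate in self.plates:
            if plate.replicate_index > self.n_replicates:
                raise PlateValidationError(
                    f"plate {plate.plate_id} has replicate_index "
                    f"{plate.replicate_index} > n_replicates={self.n_replicates}"
                )
            seen: set[str] = set()
            for w in plate.wells:
                if w.well_type is WellType.COMPOUND:
                    if w.compound_id in seen:
                        raise PlateValidationError(
                            f"compound {w.compound_id} appears more than once on "
                            f"plate {plate.plate_id}"
                        )
                    seen.add(w.compound_id)  # type: ignore[arg-type]

    def replicate_plates(self, replicate_index: int) -> list[Plate]:
        return [p for p in self.plates if p.replicate_index == replicate_index]

    def compound_ids(self) -> list[str]:
        ids: dict[str, None] = {}
        for plate in self.plates:
            for w in plate.wells:
                if w.well_type is WellType.COMPOUND and w.compound_id:
                    ids.setdefault(w.compound_id)
        return list(ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for plate in self.plates:
            for w in plate.wells:
                rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "replicate": plate.replicate_index,
                        "row": w.row,
                        "col": w.col,
                        "well_type": w.well_type.value,
                        "compound_id": w.compound_id,
                        "concentration_uM": w.concentration_uM,
                        "signal": w.signal,
                    }
                )
        return pd.DataFrame(rows, columns=PLATE_TABLE_COLUMNS)


def _well_from_row(row: pd.Series, line_no: int) -> Well:
    try:
        well_type = WellType(str(row["well_type"]))
    except ValueError as exc:
        raise PlateFormatError(
            f"row {line_no}: unknown well_type {row['well_type']!r}"
        ) from exc
    compound_id = row["compound_id"]
    if pd.isna(compound_id) or compound_id == "":
        compound_id = None
    conc = row["concentration_uM"]
    conc = None if pd.isna(conc) else float(conc)
    signal = row["signal"]
    signal = math.nan if pd.isna(signal) else float(signal)
    try:
        col = int(row["col"])
    except (TypeError, ValueError) as exc:
        raise PlateFormatError(f"row {line_no}: non-integer col {row['col']!r}") from exc
    return Well(
        plate_id=str(row["plate_id"]),
        row=str(row["row"]).strip().upper(),
        col=col,
        well_type=well_type,
        compound_id=None if compound_id is None else str(compound_id),
        concentration_uM=conc,
        signal=signal,
    )


def read_plate_table(
    path: str | Path,
    geometry: PlateGeometry = PlateGeometry.W384,
    n_replicates: int | None = None,
) -> ScreenRun:
    """Read a long-format well table into a validated :class:`ScreenRun`.

    Malformed rows raise :class:`PlateFormatError` (naming the offending
    row); invariant violations such as duplicate addresses raise
    :class:`PlateValidationError`. Wells with missing signals are kept
    and counted in a log message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        comment="#",
        dtype={"row": str, "plate_id": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in PLATE_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PlateFormatError(f"{path.name}: missing column(s) {missing_cols}")

    plates: dict[tuple[str, int], list[Well]] = {}
    for idx, row in df.iterrows():
        if pd.isna(row["plate_id"]) or pd.isna(row["replicate"]):
            raise PlateFormatError(f"row {idx + 2}: missing plate_id/replicate")
        well = _well_from_row(row, line_no=int(idx) + 2)
        plates.setdefault((str(row["plate_id"]), int(row["replicate"])), []).append(well)

    plate_objs = [
        Plate(plate_id=pid, geometry=geometry, replicate_index=rep, wells=wells)
        for (pid, rep), wells in plates.items()
    ]
    if n_replicates is None:
        n_replicates = max((p.replicate_index for p in plate_objs), default=1)
    run = ScreenRun(plates=plate_objs, n_replicates=n_replicates)

    n_missing = sum(p.n_missing for p in plate_objs)
    if n_missing:
        logger.warning(
            "%s: %d well(s) with missing signal retained and flagged", path.name, n_missing
        )
    if n_replicates > 1:
        fixed = check_randomization(run)
        if fixed:
            logger.warning(
                "%d compound(s) occupy the same well address in every replicate "
                "(e.g. %s); randomized placement expected",
                len(fixed),
                fixed[0],
            )
    return run


def write_plate_table(run: ScreenRun, path: str | Path, header_comment: str | None = None) -> None:
    """Write a :class:`ScreenRun` in canonical order (plate, row, col)."""
    df = run.to_frame().sort_values(["plate_id", "replicate", "row", "col"], kind="stable")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def control_wells(plate: Plate, kind: WellType) -> list[Well]:
    """All wells of the requested control type; empty list is legal."""
    return plate.wells_of_type(kind)


def check_randomization(run: ScreenRun) -> list[str]:
    """QC: compounds sitting at the same address in *every* replicate.

    Plate layouts are expected to re-randomize compound positions per
    replicate experiment to avoid well-location effects; a compound that
    never moves defeats that design. Returns the offending compound ids.
    """
    addresses: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for plate in run.plates:
        for w in plate.wells:
            if w.well_type is WellType.COMPOUND and w.compound_id:
                addresses.setdefault(w.compound_id, set()).add(w.address)
                counts[w.compound_id] = counts.get(w.compound_id, 0) + 1
    return sorted(
        cid
        for cid, addrs in addresses.items()
        if counts[cid] >= max(2, run.n_replicates) and len(addrs) == 1
    )
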