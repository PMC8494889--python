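import math

import pytest

from synscreen.plate_model import Plate, PlateGeometry, ScreenRun, Well, WellType


def build_plate(
    compound_signals: dict[str, float],
    control_signals: list[float],
    plate_id: str = "P1",
    replicate: int = 1,
    control_type: WellType = WellType.UNTREATED_CONTROL,
    geometry: PlateGeometry = PlateGeometry.W384,
) -> Plate:
    """Tiny plate with compounds in column 1 and controls in column 24."""
    wells = []
    rows = geometry.rows
    for i, (cid, sig) in enumerate(compound_signals.items()):
        wells.append(
            Well(plate_id, rows[i], 1, WellType.COMPOUND, compound_id=cid,
                 concentration_uM=10.0, signal=sig)
        )
    for i, sig in enumerate(control_signals):
        col = geometry.n_cols - i // len(rows)
        wells.append(Well(plate_id, rows[i % len(rows)], col, control_type, signal=sig))
    return Plate(plate_id=plate_id, geometry=geometry, replicate_index=replicate, wells=wells)


@pytest.fixture
def simple_plate() -> Plate:
    return build_plate({"A": 200.0, "B": 50.0}, [100.0, 100.0, 100.0])


@pytest.fixture
def simple_run(simple_plate) -> ScreenRun:
    return ScreenRun(plates=[simple_plate], n_replicates=1)
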