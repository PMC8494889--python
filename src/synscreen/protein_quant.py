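"""Loading- and vehicle-normalized protein quantification.

Covers the three schemes used for immunodetection readouts: Western
blots normalized to beta-actin, In-Cell Western (ICW) plates normalized
to the CellTag700 whole-cell stain, and nuclear (histone) blots
normalized to Lamin B1. In every scheme the target signal is first
divided by its loading signal, then each sample's loading-normalized
ratio is divided by the mean ratio of the vehicle (DMSO) samples of the
same batch — a membrane for blots, a plate for ICW — because loading
references are only comparable within one blot/plate.

ICW background wells (secondary antibody + CellTag only, flagged with
``compound_id == "BACKGROUND"``) are mean-subtracted per channel and
batch *before* normalization; negative post-subtraction signals clamp
to 0 with a warning.

Input tables: ``sample_id, compound_id, batch_id, target_signal,
loading_signal, loading_kind``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LoadingKind",
    "SignalPair",
    "ProteinFoldChange",
    "ProteinQuantError",
    "loading_normalize",
    "subtract_background",
    "fold_change_vs_vehicle",
    "summarize_fold_changes",
    "BACKGROUND_LABEL",
]

BACKGROUND_LABEL = "BACKGROUND"

PROTEIN_COLUMNS = [
    "sample_id",
    "compound_id",
    "batch_id",
    "target_signal",
    "loading_signal",
    "loading_kind",
]


class ProteinQuantError(ValueError):
    """Invalid protein-signal input."""


class LoadingKind(str, enum.Enum):
    ACTIN = "actin"
    CELLTAG700 = "celltag700"
    LAMIN_B1 = "laminB1"


@dataclass(frozen=True)
class SignalPair:
    sample_id: str
    compound_id: str
    target_signal: float
    loading_signal: float
    loading_kind: LoadingKind
    batch_id: str = "batch1"

    def __post_init__(self) -> None:
        if self.target_signal < 0:
            raise ProteinQuantError(
                f"{self.sample_id}: target signal must be >= 0, got {self.target_signal}"
            )
        if not self.loading_signal > 0:
            raise ProteinQuantError(
                f"{self.sample_id}: loading signal must be > 0, got {self.loading_signal}"
            )


@dataclass(frozen=True)
class ProteinFoldChange:
    """Per-compound summary of vehicle-normalized protein levels."""

    compound_id: str
    fold_change: float  # mean over samples
    n: int

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ProteinQuantError(
                f"{self.compound_id}: fold change must be > 0, got {self.fold_change}"
            )


def loading_normalize(pair: SignalPair) -> float:
    """Target ÷ loading; invariant to any common scanner-gain factor."""
    if pair.target_signal == 0:
        logger.warning("%s: zero target signal (below detection?)", pair.sample_id)
    return pair.target_signal / pair.loading_signal


def subtract_background(df: pd.DataFrame) -> pd.DataFrame:
    """Mean-subtract BACKGROUND wells per batch and channel.

    Applied before loading normalization. Rows flagged BACKGROUND are
    consumed (removed from the output); negative corrected signals
    clamp to 0 (target) or are rejected (loading — a loading signal at
    or below background means the well is unusable).
    """
    _validate_columns(df)
    out_parts: list[pd.DataFrame] = []
    for batch, group in df.groupby("batch_id", sort=True):
        bg = group[group["compound_id"] == BACKGROUND_LABEL]
        rest = group[group["compound_id"] != BACKGROUND_LABEL].copy()
        if bg.empty:
            out_parts.append(rest)
            continue
        bg_target = float(bg["target_signal"].mean())
        bg_loading = float(bg["loading_signal"].mean())
        rest["target_signal"] = rest["target_signal"] - bg_target
        rest["loading_signal"] = rest["loading_signal"] - bg_loading
        n_clamped = int((rest["target_signal"] < 0).sum())
        if n_clamped:
            logger.warning(
                "batch %s: %d target signal(s) below background clamped to 0",
                batch,
                n_clamped,
            )
            rest.loc[rest["target_signal"] < 0, "target_signal"] = 0.0
        if (rest["loading_signal"] <= 0).any():
            bad = rest.loc[rest["loading_signal"] <= 0, "sample_id"].tolist()
            raise ProteinQuantError(
                f"batch {batch}: loading signal at or below background for {bad}"
            )
        out_parts.append(rest)
    return pd.concat(out_parts, ignore_index=True)


def _validate_columns(df: pd.DataFrame) -> None:
    missing = [c for c in PROTEIN_COLUMNS if c not in df.columns]
    if missing:
        raise ProteinQuantError(f"protein table missing column(s) {missing}")


def fold_change_vs_vehicle(
    df: pd.DataFrame,
    vehicle_label: str = "DMSO",
    subtract_bg: bool = False,
) -> pd.DataFrame:
    """Per-sample fold changes versus the vehicle mean, batch-wise.

    Returns a DataFrame ``compound_id, sample_id, batch_id,
    fold_change`` covering every sample including the vehicle group
    (whose within-batch mean fold change is exactly 1 by construction).
    """
    _validate_columns(df)
    if subtract_bg:
        df = subtract_background(df)
    elif (df["compound_id"] == BACKGROUND_LABEL).any():
        df = df[df["compound_id"] != BACKGROUND_LABEL]

    rows = []
    for batch, group in df.groupby("batch_id", sort=True):
        if (group["loading_signal"] <= 0).any():
            bad = group.loc[group["loading_signal"] <= 0, "sample_id"].tolist()
            raise ProteinQuantError(f"batch {batch}: non-positive loading signal for {bad}")
        ratios = group["target_signal"] / group["loading_signal"]
        vehicle_mask = group["compound_id"] == vehicle_label
        if vehicle_mask.sum() < 2:
            raise ProteinQuantError(
                f"batch {batch}: >= 2 vehicle ({vehicle_label!r}) samples required, "
                f"got {int(vehicle_mask.sum())}"
            )
        vehicle_mean = float(ratios[vehicle_mask].mean())
        if vehicle_mean <= 0:
            raise ProteinQuantError(f"batch {batch}: vehicle mean ratio is degenerate")
        for (_, rec), ratio in zip(group.iterrows(), ratios):
            rows.append(
                {
                    "compound_id": rec["compound_id"],
                    "sample_id": rec["sample_id"],
                    "batch_id": batch,
                    "fold_change": ratio / vehicle_mean,
                }
            )
    return pd.DataFrame(rows, columns=["compound_id", "sample_id", "batch_id", "fold_change"])


def summarize_fold_changes(per_sample: pd.DataFrame) -> list[ProteinFoldChange]:
    """Collapse per-sample fold changes to one record per compound."""
    out = []
    for cid, group in per_sample.groupby("compound_id", sort=True):
        out.append(
            ProteinFoldChange(
                compound_id=str(cid),
                fold_change=float(group["fold_change"].mean()),
                n=int(len(group)),
            )
        )
    return out
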