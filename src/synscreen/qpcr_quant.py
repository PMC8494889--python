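"""Efficiency-corrected relative qPCR quantification (Pfaffl method).

Relative expression of a target gene in a treated sample versus a
control condition, normalized to one or more reference ("housekeeping")
genes:

    ratio = E_tgt ** dCT_tgt  /  geomean_r( E_r ** dCT_r )

where ``dCT = CT_control − CT_treated`` for each gene (positive when the
treated sample amplifies earlier, i.e. is up-regulated), ``E`` is the
per-gene amplification efficiency (2.0 = perfect doubling per cycle)
and the denominator is the geometric mean of the per-reference
efficiency-corrected factors. With a single reference gene and E = 2
everywhere this reduces to the classic 2^(−ddCT) formula.

Technical replicates are aggregated by arithmetic mean on the CT scale
(the measured quantity) before ratios are formed.

Input tables are long CSVs with columns
``sample_id, compound_id, condition, gene_id, ct``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QpcrSample",
    "ExpressionRatio",
    "QpcrError",
    "delta_ct",
    "pfaffl_ratio",
    "relative_expression_table",
    "per_sample_ratios",
    "DEFAULT_EFFICIENCY",
]

#: Amplification factor per cycle assumed when no standard curve is available.
DEFAULT_EFFICIENCY = 2.0

QPCR_COLUMNS = ["sample_id", "compound_id", "condition", "gene_id", "ct"]


class QpcrError(ValueError):
    """Invalid CT table or quantification parameters."""


@dataclass(frozen=True)
class QpcrSample:
    """One CT measurement (one well) of one gene in one sample."""

    sample_id: str
    condition: str
    gene_id: str
    ct: float
    compound_id: str | None = None
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise QpcrError(f"CT must be a finite positive cycle number, got {self.ct}")
        _check_efficiency(self.efficiency, self.gene_id)


@dataclass(frozen=True)
class ExpressionRatio:
    compound_id: str
    target_gene: str
    reference_genes: tuple[str, ...]
    ratio: float

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise QpcrError(f"expression ratio must be > 0, got {self.ratio}")


def _check_efficiency(e: float, gene: str = "") -> None:
    if not (1.0 < e <= 2.2):
        raise QpcrError(
            f"amplification efficiency must lie in (1, 2.2], got {e}"
            + (f" for {gene}" if gene else "")
        )


def delta_ct(control_ct: float, treated_ct: float) -> float:
    """CT difference, oriented so up-regulation is positive."""
    return control_ct - treated_ct


def pfaffl_ratio(
    target_delta_ct: float,
    reference_delta_cts: Sequence[float],
    target_efficiency: float = DEFAULT_EFFICIENCY,
    reference_efficiencies: Sequence[float] | None = None,
) -> float:
    """Efficiency-corrected ratio with geometric-mean reference aggregation."""
    refs = list(reference_delta_cts)
    if not refs:
        raise QpcrError("at least one reference gene is required")
    _check_efficiency(target_efficiency, "target")
    if reference_efficiencies is None:
        reference_efficiencies = [DEFAULT_EFFICIENCY] * len(refs)
    if len(reference_efficiencies) != len(refs):
        raise QpcrError("one efficiency per reference gene is required")
    for e in reference_efficiencies:
        _check_efficiency(e)

    # work in logs: geomean_r(E_r^d_r) = exp(mean_r(d_r * ln E_r))
    log_num = target_delta_ct * math.log(target_efficiency)
    log_den = sum(
        d * math.log(e) for d, e in zip(refs, reference_efficiencies)
    ) / len(refs)
    return math.exp(log_num - log_den)


def _validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise QpcrError(f"CT table missing column(s) {missing}")
    if df["ct"].isna().any() or not df["ct"].map(math.isfinite).all():
        raise QpcrError("CT table contains non-finite CT values")


def _mean_cts(
    df: pd.DataFrame, genes: Sequence[str], label: str
) -> dict[str, float]:
    """Technical-replicate mean CT per gene; errors name what is absent."""
    out: dict[str, float] = {}
    for gene in genes:
        sub = df[df["gene_id"] == gene]
        if sub.empty:
            raise QpcrError(f"no CT values for gene {gene} in {label}")
        out[gene] = float(sub["ct"].mean())
    return out


def relative_expression_table(
    samples: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    control_condition_label: str = "control",
    efficiencies: Mapping[str, float] | None = None,
) -> list[ExpressionRatio]:
    """One Pfaffl ratio per compound versus the pooled control condition.

    Technical replicates are mean-aggregated on the CT scale first; a
    missing (compound, gene) combination in either condition raises a
    completeness error naming it.
    """
    _validate_table(samples)
    if not reference_genes:
        raise QpcrError("at least one reference gene is required")
    efficiencies = dict(efficiencies or {})
    genes = [target_gene, *reference_genes]

    control = samples[samples["condition"] == control_condition_label]
    if control.empty:
        raise QpcrError(f"no rows with control condition {control_condition_label!r}")
    control_ct = _mean_cts(control, genes, f"condition {control_condition_label!r}")

    treated = samples[samples["condition"] != control_condition_label]
    ratios: list[ExpressionRatio] = []
    for cid, group in treated.groupby("compound_id", sort=True):
        treated_ct = _mean_cts(group, genes, f"compound {cid!r}")
        ratio = pfaffl_ratio(
            target_delta_ct=delta_ct(control_ct[target_gene], treated_ct[target_gene]),
            reference_delta_cts=[
                delta_ct(control_ct[g], treated_ct[g]) for g in reference_genes
            ],
            target_efficiency=efficiencies.get(target_gene, DEFAULT_EFFICIENCY),
            reference_efficiencies=[
                efficiencies.get(g, DEFAULT_EFFICIENCY) for g in reference_genes
            ],
        )
        ratios.append(
            ExpressionRatio(
                compound_id=str(cid),
                target_gene=target_gene,
                reference_genes=tuple(reference_genes),
                ratio=ratio,
            )
        )
    return ratios


def per_sample_ratios(
    samples: pd.DataFrame,
    target_gene: str,
    reference_genes: Sequence[str],
    control_condition_label: str = "control",
    efficiencies: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample Pfaffl ratios against the control-group mean CTs.

    Every biological/technical sample — control samples included — gets
    its own ratio, computed from that sample's CTs versus the pooled
    control mean per gene. Control-sample ratios scatter around 1 and
    provide the dispersion needed for group comparisons (e.g. Dunnett
    against the vehicle group).

    Returns a DataFrame with columns ``compound_id, sample_id, condition,
    ratio`` (control rows keep the control label as compound_id).
    """
    _validate_table(samples)
    efficiencies = dict(efficiencies or {})
    genes = [target_gene, *reference_genes]
    control = samples[samples["condition"] == control_condition_label]
    if control.empty:
        raise QpcrError(f"no rows with control condition {control_condition_label!r}")
    control_ct = _mean_cts(control, genes, f"condition {control_condition_label!r}")

    rows = []
    for (sid,), group in samples.groupby(["sample_id"], sort=True):
        sample_ct = _mean_cts(group, genes, f"sample {sid!r}")
        ratio = pfaffl_ratio(
            target_delta_ct=delta_ct(control_ct[target_gene], sample_ct[target_gene]),
            reference_delta_cts=[
                delta_ct(control_ct[g], sample_ct[g]) for g in reference_genes
            ],
            target_efficiency=efficiencies.get(target_gene, DEFAULT_EFFICIENCY),
            reference_efficiencies=[
                efficiencies.get(g, DEFAULT_EFFICIENCY) for g in reference_genes
            ],
        )
        condition = str(group["condition"].iloc[0])
        cid = group["compound_id"].iloc[0]
        cid = control_condition_label if condition == control_condition_label else str(cid)
        rows.append(
            {"compound_id": cid, "sample_id": sid, "condition": condition, "ratio": ratio}
        )
    return pd.DataFrame(rows, columns=["compound_id", "sample_id", "condition", "ratio"])
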