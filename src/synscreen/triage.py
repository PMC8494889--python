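"""Staged triage of screen hits into validated candidates.

The cascade mirrors the screening workflow: primary reporter hits are
filtered for cytotoxicity (inhibitors only — activators pass the
toxicity stage unconditionally, by the screen's stated rule), confirmed
by reporter-gene qPCR in the screening line (A1), checked for
specificity against the counter-screen line (A6, random reporter
integration: a response there flags pleiotropic transcription effects),
confirmed by target-gene qPCR in unmodified wildtype cells, and finally
confirmed at the protein level by In-Cell Western and Western blot.

A compound reaches ``final_candidates`` only by passing every stage
applicable to its class; each exclusion records the stage and reason,
and stage verdicts are append-only: once excluded, a compound is never
re-admitted. Missing data for a compound still in play is reported in
an ``incomplete`` section, never silently passed.

Statistical significance at the qPCR and protein stages is Dunnett's
test against the vehicle group on log-scale values. When every group is
exactly constant (noise-free data), the test statistic is undefined;
the stage then falls back to the exact rule "significant iff the group
mean differs from the control mean", which is the limiting behaviour
of the test as noise vanishes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
import yaml

from .hit_calling import (
    ConsensusRule,
    HitCall,
    HitClass,
    HitThreshold,
    call_hits,
    estimate_control_sd,
    normalize_run,
    rank_by_potency,
)
from .plate_model import ScreenRun, WellType
from .protein_quant import fold_change_vs_vehicle
from .qpcr_quant import per_sample_ratios
from .stats import DegenerateDataError, GroupData, dunnett_test
from .viability import (
    DEFAULT_VIABILITY_THRESHOLD,
    DoseResponseProfile,
    ToxicityCall,
    ViabilityAssay,
    ViabilityError,
    classify_toxicity,
    hcs_viability,
    resazurin_viability,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TriageConfig",
    "TriageInputs",
    "SpecificityCall",
    "TriageReport",
    "TriageError",
    "apply_toxicity_filter",
    "classify_specificity",
    "toxicity_calls_from_tables",
    "run_triage",
]

VEHICLE_LABEL = "DMSO"


class TriageError(ValueError):
    """Missing or inconsistent stage inputs."""


@dataclass
class TriageConfig:
    """Stage parameters for one triage run (YAML-loadable)."""

    k: float = 4.0
    consensus: str = "mean"
    control_type: str = "untreated_control"  # primary-screen normalization
    toxicity_threshold: float = DEFAULT_VIABILITY_THRESHOLD
    assay_concentration_uM: float = 10.0
    alpha: float = 0.05
    # counter-screen inactive band: derived from the A6 vehicle ratios
    # (1 ± k·sd) when enough controls exist, else this fixed fallback
    specificity_band: tuple[float, float] = (0.8, 1.25)
    min_band_controls: int = 4
    luc_reference_genes: tuple[str, ...] = ("UBC", "GUSB")
    snca_reference_genes: tuple[str, ...] = ("UBC", "HPRT1", "GUSB")
    target_gene_luc: str = "LUC"
    target_gene_snca: str = "SNCA"
    control_condition_label: str = VEHICLE_LABEL
    protein_rule: str = "both"  # "both" or "either" of ICW/WB must confirm
    max_inhibitors_tested: int | None = None  # potency-ranked cap, e.g. 94
    max_activators_tested: int | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "TriageConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.specificity_band, list):
            cfg.specificity_band = tuple(cfg.specificity_band)  # type: ignore[assignment]
        cfg.luc_reference_genes = tuple(cfg.luc_reference_genes)
        cfg.snca_reference_genes = tuple(cfg.snca_reference_genes)
        return cfg


@dataclass
class TriageInputs:
    """Every table the cascade consumes, keyed by assay."""

    screen: ScreenRun
    resazurin: pd.DataFrame  # compound_id, concentration_uM, signal (+ DMSO rows)
    hcs: pd.DataFrame  # compound_id, concentration_uM, live, dead
    luc_qpcr_a1: pd.DataFrame  # sample_id, compound_id, condition, gene_id, ct
    luc_qpcr_a6: pd.DataFrame
    snca_qpcr_wt: pd.DataFrame
    protein_icw: pd.DataFrame  # sample_id, compound_id, batch_id, target/loading, kind
    protein_wb: pd.DataFrame


@dataclass(frozen=True)
class SpecificityCall:
    compound_id: str
    a1_ratio: float
    a6_ratio: float
    a1_significant: bool
    specific: bool


@dataclass
class TriageReport:
    threshold: dict
    stages: dict[str, dict]  # per-compound verdict per stage
    exclusions: dict[str, dict]  # compound -> {stage, reason}
    incomplete: dict[str, str]  # compound -> missing-data description
    final_candidates: list[str]
    n_compounds: int

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "threshold": self.threshold,
            "stages": self.stages,
            "exclusions": self.exclusions,
            "incomplete": self.incomplete,
            "final_candidates": self.final_candidates,
            "n_compounds": self.n_compounds,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def apply_toxicity_filter(
    hits: list[HitCall],
    toxicity: Mapping[str, ToxicityCall],
) -> list[HitCall]:
    """Drop toxic inhibitors; activators pass unconditionally.

    An inhibitor without a toxicity call is a coverage error — a
    missing viability measurement must never look like a pass.
    """
    out: list[HitCall] = []
    for hit in hits:
        if hit.classification is HitClass.INHIBITOR:
            call = toxicity.get(hit.compound_id)
            if call is None:
                raise TriageError(
                    f"inhibitor {hit.compound_id} has no toxicity call; "
                    "viability coverage is required for every tested inhibitor"
                )
            if call.toxic:
                continue
        elif hit.classification is HitClass.ACTIVATOR:
            call = toxicity.get(hit.compound_id)
            if call is not None and call.toxic:
                logger.info(
                    "activator %s is flagged toxic but passes the filter "
                    "(activators are exempt by design)",
                    hit.compound_id,
                )
        out.append(hit)
    return out


def classify_specificity(
    compound_id: str,
    a1_ratio: float,
    a1_significant: bool,
    a6_ratio: float | None,
    inactive_band: tuple[float, float],
) -> SpecificityCall:
    """Specific iff the screening-line response is significant AND the
    counter-screen ratio sits inside the inactive band."""
    if a6_ratio is None or not math.isfinite(a6_ratio):
        raise TriageError(f"{compound_id}: counter-screen (A6) ratio is missing")
    lo, hi = inactive_band
    specific = bool(a1_significant and lo <= a6_ratio <= hi)
    return SpecificityCall(
        compound_id=compound_id,
        a1_ratio=a1_ratio,
        a6_ratio=a6_ratio,
        a1_significant=a1_significant,
        specific=specific,
    )


# ---------------------------------------------------------------------------
# stage helpers


def toxicity_calls_from_tables(
    resazurin: pd.DataFrame,
    hcs: pd.DataFrame,
    assay_concentration: float,
    threshold: float,
    vehicle_label: str = VEHICLE_LABEL,
) -> dict[str, ToxicityCall]:
    """Build per-compound dose–response profiles and classify them."""
    controls = resazurin[resazurin["compound_id"] == vehicle_label]["signal"].tolist()
    calls: dict[str, ToxicityCall] = {}
    compounds = sorted(
        set(resazurin["compound_id"]) - {vehicle_label}
    )
    for cid in compounds:
        res_rows = resazurin[resazurin["compound_id"] == cid]
        points = []
        for conc, grp in res_rows.groupby("concentration_uM", sort=True):
            v = resazurin_viability(grp["signal"].tolist(), controls, label=f"{cid}@{conc}uM")
            points.append((float(conc), v))
        profiles = [
            DoseResponseProfile(cid, ViabilityAssay.RESAZURIN, tuple(points))
        ]
        hcs_rows = hcs[hcs["compound_id"] == cid]
        if not hcs_rows.empty:
            pts = []
            for conc, grp in hcs_rows.groupby("concentration_uM", sort=True):
                live = int(grp["live"].sum())
                dead = int(grp["dead"].sum())
                pts.append((float(conc), hcs_viability(live, dead)))
            profiles.append(DoseResponseProfile(cid, ViabilityAssay.HCS_COUNT, tuple(pts)))
        calls[cid] = classify_toxicity(profiles, assay_concentration, threshold)
    return calls


def _dunnett_significance(
    per_sample: pd.DataFrame,
    value_col: str,
    control_label: str,
    alpha: float,
    log_scale: bool = True,
) -> dict[str, tuple[bool, float]]:
    """Per-compound (significant, adjusted_p) versus the vehicle group.

    Values are compared on the log scale (ratios are multiplicative).
    Noise-free inputs make every within-group variance zero; the exact
    zero-noise limit is then used: significant iff mean != control mean.
    """
    groups: list[GroupData] = []
    for cid, grp in per_sample.groupby("compound_id", sort=True):
        values = grp[value_col].astype(float)
        if log_scale:
            values = values.map(math.log)
        if len(values) >= 2:
            groups.append(
                GroupData(str(cid), tuple(values), is_control=(cid == control_label))
            )
    if not any(g.is_control for g in groups):
        raise TriageError(f"no {control_label!r} control group in per-sample table")
    control = next(g for g in groups if g.is_control)
    treatments = [g for g in groups if not g.is_control]
    if not treatments:
        return {}
    try:
        results = dunnett_test(groups)
        return {r.group_id: (r.adjusted_p < alpha, r.adjusted_p) for r in results}
    except DegenerateDataError:
        logger.info("zero within-group variance; using exact zero-noise significance rule")
        return {
            g.group_id: (not math.isclose(g.mean, control.mean, abs_tol=1e-12), 0.0)
            for g in treatments
        }


def _mean_ratios(per_sample: pd.DataFrame, control_label: str) -> dict[str, float]:
    return {
        str(cid): float(grp["ratio"].mean())
        for cid, grp in per_sample.groupby("compound_id", sort=True)
        if cid != control_label
    }


def _specificity_band(
    a6_per_sample: pd.DataFrame, config: TriageConfig
) -> tuple[float, float]:
    """Inactive band from the A6 vehicle ratios (1 ± k·sd), with a fixed
    fallback when control replication is too sparse."""
    controls = a6_per_sample[
        a6_per_sample["compound_id"] == config.control_condition_label
    ]["ratio"]
    if len(controls) >= config.min_band_controls:
        sd = float(controls.std(ddof=1))
        if math.isfinite(sd):
            return (1.0 - config.k * sd, 1.0 + config.k * sd)
    return config.specificity_band


# ---------------------------------------------------------------------------
# cascade


def run_triage(inputs: TriageInputs, config: TriageConfig | None = None) -> TriageReport:
    """Run the full cascade and emit a per-compound audit trail."""
    config = config or TriageConfig()
    stages: dict[str, dict] = {}
    exclusions: dict[str, dict] = {}
    incomplete: dict[str, str] = {}

    def exclude(cid: str, stage: str, reason: str) -> None:
        if cid not in exclusions:  # append-only: first exclusion wins
            exclusions[cid] = {"stage": stage, "reason": reason}

    # --- stage 1: primary reporter screen -------------------------------
    records = normalize_run(inputs.screen, WellType(config.control_type))
    threshold = estimate_control_sd(records, k=config.k, control_type=WellType(config.control_type))
    calls = call_hits(records, threshold, ConsensusRule(config.consensus))
    calls.sort(key=lambda c: c.compound_id)
    stages["luc_class"] = {
        c.compound_id: {
            "classification": c.classification.value,
            "mean_fold_change": c.mean_fold_change,
        }
        for c in calls
    }
    hits = [c for c in calls if c.classification is not HitClass.INACTIVE]
    for c in calls:
        if c.classification is HitClass.INACTIVE:
            exclude(c.compound_id, "luc_class", "inactive in primary screen")

    # optional potency-ranked caps on what proceeds to follow-up assays
    inhibitors = [c for c in hits if c.classification is HitClass.INHIBITOR]
    activators = [c for c in hits if c.classification is HitClass.ACTIVATOR]
    if config.max_inhibitors_tested is not None:
        kept = rank_by_potency(inhibitors)[: config.max_inhibitors_tested]
        for c in inhibitors:
            if c not in kept:
                exclude(c.compound_id, "selection", "below potency cap for inhibitors")
        inhibitors = kept
    if config.max_activators_tested is not None:
        kept = rank_by_potency(activators)[: config.max_activators_tested]
        for c in activators:
            if c not in kept:
                exclude(c.compound_id, "selection", "below potency cap for activators")
        activators = kept
    hits = sorted(inhibitors + activators, key=lambda c: c.compound_id)

    # --- stage 2: toxicity (inhibitors only) ----------------------------
    try:
        tox_calls = toxicity_calls_from_tables(
            inputs.resazurin,
            inputs.hcs,
            config.assay_concentration_uM,
            config.toxicity_threshold,
            config.control_condition_label,
        )
    except ViabilityError as exc:
        raise TriageError(f"viability stage failed: {exc}") from exc
    stages["toxicity"] = {
        cid: {"toxic": call.toxic, "min_toxic_concentration": call.min_toxic_concentration}
        for cid, call in sorted(tox_calls.items())
    }
    survivors = apply_toxicity_filter(hits, tox_calls)
    for hit in hits:
        if hit not in survivors:
            exclude(hit.compound_id, "toxicity", "toxic inhibitor")
    classes = {c.compound_id: c.classification for c in survivors}

    # --- stage 3: reporter qPCR in the screening line (A1) --------------
    a1 = per_sample_ratios(
        inputs.luc_qpcr_a1,
        config.target_gene_luc,
        config.luc_reference_genes,
        config.control_condition_label,
    )
    a1_sig = _dunnett_significance(a1, "ratio", config.control_condition_label, config.alpha)
    a1_ratio = _mean_ratios(a1, config.control_condition_label)
    stages["luc_qpcr_a1"] = {
        cid: {"ratio": a1_ratio[cid], "significant": a1_sig[cid][0], "adjusted_p": a1_sig[cid][1]}
        for cid in sorted(a1_ratio)
        if cid in a1_sig
    }
    in_play = []
    for hit in survivors:
        cid = hit.compound_id
        if cid not in a1_ratio or cid not in a1_sig:
            incomplete[cid] = "no screening-line (A1) qPCR data"
            continue
        sig, _ = a1_sig[cid]
        ratio = a1_ratio[cid]
        direction_ok = (
            ratio > 1.0 if classes[cid] is HitClass.ACTIVATOR else ratio < 1.0
        )
        if sig and direction_ok:
            in_play.append(hit)
        else:
            exclude(cid, "luc_qpcr_a1", "no significant reporter mRNA change in expected direction")
    survivors = in_play

    # --- stage 4: counter-screen specificity (A6) -----------------------
    a6 = per_sample_ratios(
        inputs.luc_qpcr_a6,
        config.target_gene_luc,
        config.luc_reference_genes,
        config.control_condition_label,
    )
    a6_ratio = _mean_ratios(a6, config.control_condition_label)
    band = _specificity_band(a6, config)
    stages["specificity_a6"] = {}
    in_play = []
    for hit in survivors:
        cid = hit.compound_id
        if cid not in a6_ratio:
            incomplete[cid] = "no counter-screen (A6) qPCR data"
            continue
        call = classify_specificity(
            cid, a1_ratio[cid], a1_sig[cid][0], a6_ratio[cid], band
        )
        stages["specificity_a6"][cid] = {
            "a6_ratio": call.a6_ratio,
            "band": list(band),
            "specific": call.specific,
        }
        if call.specific:
            in_play.append(hit)
        else:
            exclude(cid, "specificity_a6", "counter-screen response outside inactive band")
    survivors = in_play

    # --- stage 5: target-gene qPCR in wildtype cells --------------------
    wt = per_sample_ratios(
        inputs.snca_qpcr_wt,
        config.target_gene_snca,
        config.snca_reference_genes,
        config.control_condition_label,
    )
    wt_sig = _dunnett_significance(wt, "ratio", config.control_condition_label, config.alpha)
    wt_ratio = _mean_ratios(wt, config.control_condition_label)
    stages["snca_qpcr_wt"] = {
        cid: {"ratio": wt_ratio[cid], "significant": wt_sig[cid][0]}
        for cid in sorted(wt_ratio)
        if cid in wt_sig
    }
    in_play = []
    for hit in survivors:
        cid = hit.compound_id
        if cid not in wt_ratio or cid not in wt_sig:
            incomplete[cid] = "no wildtype target-gene qPCR data"
            continue
        direction_ok = (
            wt_ratio[cid] > 1.0
            if classes[cid] is HitClass.ACTIVATOR
            else wt_ratio[cid] < 1.0
        )
        if wt_sig[cid][0] and direction_ok:
            in_play.append(hit)
        else:
            exclude(cid, "snca_qpcr_wt", "no significant target mRNA change in wildtype cells")
    survivors = in_play

    # --- stage 6: protein confirmation (ICW and/or WB) ------------------
    measurements: dict[str, dict[str, tuple[bool, float]]] = {}
    for name, table in (("protein_icw", inputs.protein_icw), ("protein_wb", inputs.protein_wb)):
        per_sample = fold_change_vs_vehicle(
            table, vehicle_label=config.control_condition_label, subtract_bg=(name == "protein_icw")
        )
        sig = _dunnett_significance(
            per_sample, "fold_change", config.control_condition_label, config.alpha
        )
        means = {
            str(cid): float(grp["fold_change"].mean())
            for cid, grp in per_sample.groupby("compound_id", sort=True)
            if cid != config.control_condition_label
        }
        stages[name] = {
            cid: {"fold_change": means[cid], "significant": sig[cid][0]}
            for cid in sorted(means)
            if cid in sig
        }
        for cid, m in means.items():
            if cid in sig:
                measurements.setdefault(cid, {})[name] = (sig[cid][0], m)

    final: list[str] = []
    for hit in survivors:
        cid = hit.compound_id
        meas = measurements.get(cid)
        if meas is None or len(meas) < 2:
            incomplete[cid] = "missing protein (ICW/WB) data"
            continue
        want_up = classes[cid] is HitClass.ACTIVATOR
        confirmed = [
            significant and ((mean > 1.0) if want_up else (mean < 1.0))
            for significant, mean in meas.values()
        ]
        ok = all(confirmed) if config.protein_rule == "both" else any(confirmed)
        if ok:
            final.append(cid)
        else:
            exclude(cid, "protein", "protein change not confirmed")

    return TriageReport(
        threshold={
            "control_sd": threshold.control_sd,
            "k": threshold.k,
            "lower_bound": threshold.lower_bound,
            "upper_bound": threshold.upper_bound,
        },
        stages=stages,
        exclusions=exclusions,
        incomplete=incomplete,
        final_candidates=sorted(final),
        n_compounds=len(calls),
    )
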