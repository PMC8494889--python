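"""Synthetic screen generator with known ground truth.

Emulates the study design end to end: 384-well plates with a fixed
control block and compound positions re-randomized for each of three
replicate experiments; multiplicative log-normal well noise and a
per-plate gain factor; dose-dependent toxicity following a Hill curve
sampled by a resazurin table and a live/dead count table; CT tables for
a target gene plus housekeeping references in the screening (A1),
counter-screen (A6) and wildtype lines; and protein signal tables for
ICW and Western blot. Every generated bundle carries a ground-truth
table so round-trip tests can compare pipeline output against the
spiked effects — the truth is always a separate artifact, never a
column of an assay table.

Effect magnitudes default to the validated ranges of the study system:
activator reporter/mRNA fold changes in 1.4–2.0 and protein fold
changes in 1.3–2.0.

All randomness flows from the mandatory ``NoiseModel.seed``; each
generator draws from an independent, deterministically derived stream,
so identical seed + parameters reproduce every file byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_model import Plate, PlateGeometry, ScreenRun, Well, WellType
from .triage import TriageInputs

__all__ = [
    "EffectModel",
    "NoiseModel",
    "LayoutError",
    "make_study_effects",
    "make_spiked_effects",
    "hill_viability",
    "generate_screen",
    "generate_dose_response",
    "generate_ct_table",
    "generate_protein_table",
    "generate_triage_bundle",
    "truth_table",
    "write_bundle",
    "DEFAULT_CONCENTRATIONS_UM",
    "DEFAULT_BASE_CT",
    "VEHICLE_LABEL",
]

VEHICLE_LABEL = "DMSO"

#: Dose series inside the tested 0.25–40 uM range, bracketing the
#: 10 uM screening concentration.
DEFAULT_CONCENTRATIONS_UM = (0.25, 1.0, 2.5, 5.0, 10.0, 25.0, 40.0)

#: Plausible crossing cycles for an abundant target and mid/high-copy
#: housekeeping genes.
DEFAULT_BASE_CT: Mapping[str, float] = {
    "LUC": 24.0,
    "SNCA": 24.0,
    "UBC": 20.0,
    "GUSB": 25.0,
    "HPRT1": 26.0,
}

# stream ids: one independent RNG substream per generated artifact kind
_STREAM_EFFECTS = 0
_STREAM_SCREEN = 1
_STREAM_DOSE = 2
_STREAM_CT = 3
_STREAM_PROTEIN = 4


class LayoutError(ValueError):
    """Compounds do not fit the plate geometry / control layout."""


@dataclass(frozen=True)
class EffectModel:
    """Ground-truth effect of one compound.

    ``specific`` True means the compound acts through the target locus
    and perturbs the screening line only; False means a pleiotropic
    transcriptional effect that shows up in the counter-screen line
    too. Inert compounds have every fold change at 1 and no toxicity.
    """

    compound_id: str
    true_luc_fc: float = 1.0
    specific: bool = True
    toxic_ic: float | None = None  # Hill midpoint, uM
    hill_slope: float = 2.0
    true_mrna_fc: float = 1.0
    true_protein_fc: float = 1.0

    def __post_init__(self) -> None:
        if self.true_luc_fc <= 0 or self.true_mrna_fc <= 0 or self.true_protein_fc <= 0:
            raise ValueError(f"{self.compound_id}: fold changes must be positive")
        if self.toxic_ic is not None and self.toxic_ic <= 0:
            raise ValueError(f"{self.compound_id}: toxic_ic must be positive")
        if self.is_inert and self.toxic_ic is not None:
            raise ValueError(f"{self.compound_id}: inert compounds cannot be toxic")

    @property
    def is_inert(self) -> bool:
        return (
            self.true_luc_fc == 1.0
            and self.true_mrna_fc == 1.0
            and self.true_protein_fc == 1.0
        )

    def luc_fc(self, line: str) -> float:
        """Reporter fold change in a given cell line ('A1' or 'A6')."""
        if line == "A6" and self.specific:
            return 1.0
        return self.true_luc_fc

    def mrna_fc(self, line: str) -> float:
        if line == "A6" and self.specific:
            return 1.0
        return self.true_mrna_fc


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion parameters; the seed is mandatory by design."""

    seed: int
    well_cv: float = 0.08  # log-normal well-to-well CV
    plate_factor_sd: float = 0.10  # per-plate multiplicative gain CV
    ct_sd: float = 0.15  # cycles
    count_n: int = 500  # expected cells per imaged well

    def __post_init__(self) -> None:
        for name in ("well_cv", "plate_factor_sd", "ct_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.count_n <= 0:
            raise ValueError("count_n must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


# ---------------------------------------------------------------------------
# effect tables


def make_study_effects(
    n_compounds: int = 500,
    n_specific_activators: int = 3,
    n_pleiotropic_activators: int = 2,
    n_toxic_inhibitors: int = 5,
    n_nontoxic_inhibitors: int = 0,
    seed: int = 0,
) -> list[EffectModel]:
    """A compound library shaped like the study's validated effects.

    Activator reporter/mRNA fold changes are drawn from U(1.4, 2.0) and
    protein fold changes from U(1.3, 2.0); inhibitors mirror those
    ranges below 1. Toxic compounds get a Hill midpoint below the 10 uM
    screening dose so they are toxic at screen-relevant concentrations.
    """
    n_active = (
        n_specific_activators
        + n_pleiotropic_activators
        + n_toxic_inhibitors
        + n_nontoxic_inhibitors
    )
    if n_active > n_compounds:
        raise ValueError("more active compounds requested than library size")
    rng = np.random.default_rng([int(seed), _STREAM_EFFECTS])
    effects: list[EffectModel] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"C{idx:04d}"

    for _ in range(n_specific_activators):
        effects.append(
            EffectModel(
                compound_id=next_id(),
                true_luc_fc=float(rng.uniform(1.4, 2.0)),
                specific=True,
                true_mrna_fc=float(rng.uniform(1.4, 2.0)),
                true_protein_fc=float(rng.uniform(1.3, 2.0)),
            )
        )
    for _ in range(n_pleiotropic_activators):
        effects.append(
            EffectModel(
                compound_id=next_id(),
                true_luc_fc=float(rng.uniform(1.4, 2.0)),
                specific=False,
                true_mrna_fc=float(rng.uniform(1.4, 2.0)),
                true_protein_fc=float(rng.uniform(1.3, 2.0)),
            )
        )
    for _ in range(n_toxic_inhibitors):
        effects.append(
            EffectModel(
                compound_id=next_id(),
                true_luc_fc=float(rng.uniform(0.4, 0.65)),
                specific=True,
                toxic_ic=float(rng.uniform(1.0, 6.0)),
                true_mrna_fc=float(rng.uniform(0.4, 0.65)),
                true_protein_fc=float(rng.uniform(0.5, 0.8)),
            )
        )
    for _ in range(n_nontoxic_inhibitors):
        effects.append(
            EffectModel(
                compound_id=next_id(),
                true_luc_fc=float(rng.uniform(0.4, 0.65)),
                specific=True,
                true_mrna_fc=float(rng.uniform(0.4, 0.65)),
                true_protein_fc=float(rng.uniform(0.5, 0.8)),
            )
        )
    for _ in range(n_compounds - n_active):
        effects.append(EffectModel(compound_id=next_id()))
    return effects


def make_spiked_effects(
    n_compounds: int = 500,
    n_spiked: int = 20,
    spiked_fc: float = 1.6,
) -> list[EffectModel]:
    """Operating-characteristics library: the first ``n_spiked``
    compounds carry a fixed reporter fold change, the rest are inert."""
    if n_spiked > n_compounds:
        raise ValueError("n_spiked cannot exceed n_compounds")
    effects = [
        EffectModel(
            compound_id=f"C{i + 1:04d}",
            true_luc_fc=spiked_fc,
            true_mrna_fc=spiked_fc,
            true_protein_fc=spiked_fc,
        )
        for i in range(n_spiked)
    ]
    effects.extend(
        EffectModel(compound_id=f"C{i + 1:04d}") for i in range(n_spiked, n_compounds)
    )
    return effects


# ---------------------------------------------------------------------------
# screen plates


def _control_layout(
    geometry: PlateGeometry,
    n_untreated: int,
    n_vehicle: int,
    n_positive: int,
) -> dict[tuple[str, int], WellType]:
    """Fixed control block in the last two columns, filled top-down."""
    addresses = [
        (row, col)
        for col in (geometry.n_cols - 1, geometry.n_cols)
        for row in geometry.rows
    ]
    n_controls = n_untreated + n_vehicle + n_positive
    if n_controls > len(addresses):
        raise LayoutError(
            f"{n_controls} control wells do not fit the {len(addresses)}-well "
            "control block (last two columns)"
        )
    layout: dict[tuple[str, int], WellType] = {}
    it = iter(addresses)
    for _ in range(n_untreated):
        layout[next(it)] = WellType.UNTREATED_CONTROL
    for _ in range(n_vehicle):
        layout[next(it)] = WellType.VEHICLE_CONTROL
    for _ in range(n_positive):
        layout[next(it)] = WellType.POSITIVE_CONTROL
    return layout


def generate_screen(
    effects: Sequence[EffectModel],
    noise: NoiseModel,
    geometry: PlateGeometry = PlateGeometry.W384,
    n_replicates: int = 3,
    n_untreated_controls: int = 22,
    n_vehicle_controls: int = 6,
    n_positive_controls: int = 2,
    concentration_uM: float = 10.0,
    base_signal: float = 1000.0,
    positive_control_fc: float = 1.5,
    cell_line: str = "A1",
) -> ScreenRun:
    """Replicated screen plates with re-randomized compound placement.

    Controls occupy a fixed block (identical across plates and
    replicates); compounds are shuffled into the remaining wells anew
    for every replicate. Well signal = base x plate gain x true fold
    change x mean-one log-normal noise.
    """
    layout = _control_layout(
        geometry, n_untreated_controls, n_vehicle_controls, n_positive_controls
    )
    compound_addresses = [
        (row, col)
        for col in range(1, geometry.n_cols + 1)
        for row in geometry.rows
        if (row, col) not in layout and col <= geometry.n_cols - 2
    ]
    per_plate = len(compound_addresses)
    if per_plate == 0:
        raise LayoutError("control block leaves no room for compounds")
    n_plates = math.ceil(len(effects) / per_plate)

    rng = noise.rng(_STREAM_SCREEN)
    plates: list[Plate] = []
    for rep in range(1, n_replicates + 1):
        order = rng.permutation(len(effects))
        for p in range(n_plates):
            plate_id = f"{cell_line}-R{rep}-P{p + 1:02d}"
            plate_factor = float(_lognormal_factor(rng, noise.plate_factor_sd, 1)[0])
            chunk = order[p * per_plate : (p + 1) * per_plate]
            well_noise = _lognormal_factor(rng, noise.well_cv, len(layout) + len(chunk))
            wells: list[Well] = []
            for i, ((row, col), wtype) in enumerate(layout.items()):
                fc = positive_control_fc if wtype is WellType.POSITIVE_CONTROL else 1.0
                sig = base_signal * plate_factor * fc * float(well_noise[i])
                wells.append(Well(plate_id, row, col, wtype, signal=sig))
            for addr_idx, eff_idx in enumerate(chunk):
                eff = effects[eff_idx]
                row, col = compound_addresses[addr_idx]
                sig = (
                    base_signal
                    * plate_factor
                    * eff.luc_fc(cell_line)
                    * float(well_noise[len(layout) + addr_idx])
                )
                wells.append(
                    Well(
                        plate_id,
                        row,
                        col,
                        WellType.COMPOUND,
                        compound_id=eff.compound_id,
                        concentration_uM=concentration_uM,
                        signal=sig,
                    )
                )
            plates.append(
                Plate(plate_id=plate_id, geometry=geometry, replicate_index=rep, wells=wells)
            )
    catalog = {e.compound_id: {"library": "synthetic"} for e in effects}
    return ScreenRun(plates=plates, n_replicates=n_replicates, compound_catalog=catalog)


# ---------------------------------------------------------------------------
# dose-response viability


def hill_viability(effect: EffectModel, concentration_uM: float) -> float:
    """Noise-free viability: 1 / (1 + (c / IC)^slope), 1 if non-toxic."""
    if effect.toxic_ic is None:
        return 1.0
    return 1.0 / (1.0 + (concentration_uM / effect.toxic_ic) ** effect.hill_slope)


def generate_dose_response(
    effects: Sequence[EffectModel],
    noise: NoiseModel,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    n_replicates: int = 2,
    n_vehicle_wells: int = 6,
    base_signal: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resazurin and live/dead-count tables over the dose series.

    Returns ``(resazurin, hcs)``. The resazurin table carries vehicle
    rows (compound_id DMSO, concentration 0). At zero well noise the
    HCS counts are the deterministic rounding of count_n x viability,
    so noise-free round trips are exact.
    """
    concs = list(concentrations)
    if any(c <= 0 for c in concs) or any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be positive and strictly increasing")
    rng = noise.rng(_STREAM_DOSE)
    res_rows = []
    hcs_rows = []
    for i in range(n_vehicle_wells):
        sig = base_signal * float(_lognormal_factor(rng, noise.well_cv, 1)[0])
        res_rows.append(
            {"compound_id": VEHICLE_LABEL, "concentration_uM": 0.0, "signal": sig}
        )
    for eff in effects:
        for c in concs:
            v = hill_viability(eff, c)
            for _ in range(n_replicates):
                sig = base_signal * v * float(_lognormal_factor(rng, noise.well_cv, 1)[0])
                res_rows.append(
                    {"compound_id": eff.compound_id, "concentration_uM": c, "signal": sig}
                )
            if noise.well_cv == 0:
                total = noise.count_n
                live = round(noise.count_n * v)
            else:
                total = max(1, int(rng.poisson(noise.count_n)))
                live = int(rng.binomial(total, v))
            hcs_rows.append(
                {
                    "compound_id": eff.compound_id,
                    "concentration_uM": c,
                    "live": live,
                    "dead": total - live,
                }
            )
    return pd.DataFrame(res_rows), pd.DataFrame(hcs_rows)


# ---------------------------------------------------------------------------
# CT tables


def generate_ct_table(
    effects: Sequence[EffectModel],
    noise: NoiseModel,
    target_gene: str,
    reference_genes: Sequence[str],
    base_ct: Mapping[str, float] = DEFAULT_BASE_CT,
    line: str = "A1",
    n_replicates: int = 3,
    n_control_samples: int = 6,
    efficiency: float = 2.0,
    stream_offset: int = 0,
) -> pd.DataFrame:
    """CT table: treated target CT = base − log_E(fold change) + noise.

    Reference-gene CTs are untouched by compound effects. In the
    counter-screen line specific compounds leave the target at
    baseline; pleiotropic ones shift it there too.
    """
    genes = [target_gene, *reference_genes]
    for g in genes:
        if g not in base_ct:
            raise ValueError(f"no base CT for gene {g}")
        if not (10.0 < base_ct[g] < 35.0):
            raise ValueError(f"base CT for {g} must lie in (10, 35)")
    rng = noise.rng(_STREAM_CT + 10 * (1 + stream_offset))
    log_e = math.log(efficiency)

    def ct_noise() -> float:
        return float(rng.normal(0.0, noise.ct_sd)) if noise.ct_sd > 0 else 0.0

    rows = []
    for i in range(n_control_samples):
        sid = f"{line}-{VEHICLE_LABEL}-{i + 1}"
        for g in genes:
            rows.append(
                {
                    "sample_id": sid,
                    "compound_id": VEHICLE_LABEL,
                    "condition": VEHICLE_LABEL,
                    "gene_id": g,
                    "ct": base_ct[g] + ct_noise(),
                }
            )
    for eff in effects:
        shift = math.log(eff.mrna_fc(line)) / log_e  # cycles earlier if up
        for r in range(n_replicates):
            sid = f"{line}-{eff.compound_id}-{r + 1}"
            for g in genes:
                ct = base_ct[g] - (shift if g == target_gene else 0.0) + ct_noise()
                rows.append(
                    {
                        "sample_id": sid,
                        "compound_id": eff.compound_id,
                        "condition": "treated",
                        "gene_id": g,
                        "ct": ct,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "compound_id", "condition", "gene_id", "ct"])


# ---------------------------------------------------------------------------
# protein tables


def generate_protein_table(
    effects: Sequence[EffectModel],
    noise: NoiseModel,
    assay: str = "icw",  # "icw" (CellTag700, with background wells) or "wb" (actin)
    n_replicates: int = 6,
    n_vehicle: int = 6,
    base_target: float = 2000.0,
    base_loading: float = 5000.0,
    background_target: float = 150.0,
    background_loading: float = 300.0,
    n_background_wells: int = 4,
    batch_id: str = "batch1",
    stream_offset: int = 0,
) -> pd.DataFrame:
    """Target/loading signal pairs with a spiked true protein effect.

    ICW rows include additive background (and dedicated BACKGROUND
    wells to estimate it); WB rows are background-free.
    """
    if assay not in ("icw", "wb"):
        raise ValueError("assay must be 'icw' or 'wb'")
    loading_kind = "celltag700" if assay == "icw" else "actin"
    rng = noise.rng(_STREAM_PROTEIN + 10 * (1 + stream_offset))
    bg_t = background_target if assay == "icw" else 0.0
    bg_l = background_loading if assay == "icw" else 0.0

    rows = []

    def emit(cid: str, sid: str, fc: float) -> None:
        t = bg_t + base_target * fc * float(_lognormal_factor(rng, noise.well_cv, 1)[0])
        ld = bg_l + base_loading * float(_lognormal_factor(rng, noise.well_cv, 1)[0])
        rows.append(
            {
                "sample_id": sid,
                "compound_id": cid,
                "batch_id": batch_id,
                "target_signal": t,
                "loading_signal": ld,
                "loading_kind": loading_kind,
            }
        )

    for i in range(n_vehicle):
        emit(VEHICLE_LABEL, f"{assay}-{VEHICLE_LABEL}-{i + 1}", 1.0)
    for eff in effects:
        for r in range(n_replicates):
            emit(eff.compound_id, f"{assay}-{eff.compound_id}-{r + 1}", eff.true_protein_fc)
    if assay == "icw":
        for i in range(n_background_wells):
            rows.append(
                {
                    "sample_id": f"{assay}-bg-{i + 1}",
                    "compound_id": "BACKGROUND",
                    "batch_id": batch_id,
                    "target_signal": bg_t,
                    "loading_signal": bg_l,
                    "loading_kind": loading_kind,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "compound_id",
            "batch_id",
            "target_signal",
            "loading_signal",
            "loading_kind",
        ],
    )


# ---------------------------------------------------------------------------
# full bundle + truth


def generate_triage_bundle(
    effects: Sequence[EffectModel],
    noise: NoiseModel,
    followup: Sequence[str] | None = None,
    **screen_kwargs,
) -> TriageInputs:
    """Everything the triage cascade consumes, from one effect table.

    ``followup`` names the compounds that get qPCR and protein tables
    (defaults to every compound with a non-unit effect, emulating that
    only screen hits are carried into validation assays). Viability
    tables cover the whole library.
    """
    screen = generate_screen(effects, noise, cell_line="A1", **screen_kwargs)
    resazurin, hcs = generate_dose_response(effects, noise)
    if followup is None:
        followup_effects = [e for e in effects if not e.is_inert]
    else:
        wanted = set(followup)
        followup_effects = [e for e in effects if e.compound_id in wanted]
    luc_a1 = generate_ct_table(
        followup_effects, noise, "LUC", ("UBC", "GUSB"), line="A1", stream_offset=0
    )
    luc_a6 = generate_ct_table(
        followup_effects, noise, "LUC", ("UBC", "GUSB"), line="A6", stream_offset=1
    )
    snca_wt = generate_ct_table(
        followup_effects, noise, "SNCA", ("UBC", "HPRT1", "GUSB"), line="WT", stream_offset=2
    )
    icw = generate_protein_table(followup_effects, noise, assay="icw", stream_offset=0)
    wb = generate_protein_table(followup_effects, noise, assay="wb", stream_offset=1)
    return TriageInputs(
        screen=screen,
        resazurin=resazurin,
        hcs=hcs,
        luc_qpcr_a1=luc_a1,
        luc_qpcr_a6=luc_a6,
        snca_qpcr_wt=snca_wt,
        protein_icw=icw,
        protein_wb=wb,
    )


def truth_table(
    effects: Sequence[EffectModel],
    assay_concentration_uM: float = 10.0,
    viability_threshold: float = 0.70,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
) -> pd.DataFrame:
    """Ground-truth labels under the pipeline's own decision rules.

    ``luc_class`` is the sign of the true reporter effect;
    ``toxic_at_assay`` applies the viability rule to the noise-free
    Hill curve over the tested dose series; ``final_candidate`` marks
    specific activators that are non-toxic with elevated mRNA and
    protein — the set a perfect pipeline must recover.
    """
    rows = []
    for eff in effects:
        if eff.true_luc_fc > 1.0:
            luc_class = "activator"
        elif eff.true_luc_fc < 1.0:
            luc_class = "inhibitor"
        else:
            luc_class = "inactive"
        toxic = any(
            hill_viability(eff, c) < viability_threshold
            for c in concentrations
            if c <= assay_concentration_uM
        )
        if luc_class == "activator":
            confirmed = eff.true_mrna_fc > 1.0 and eff.true_protein_fc > 1.0
        elif luc_class == "inhibitor":
            confirmed = eff.true_mrna_fc < 1.0 and eff.true_protein_fc < 1.0
        else:
            confirmed = False
        final = eff.specific and not toxic and confirmed
        rows.append(
            {
                "compound_id": eff.compound_id,
                "true_luc_fc": eff.true_luc_fc,
                "specific": eff.specific,
                "toxic_ic": eff.toxic_ic,
                "hill_slope": eff.hill_slope,
                "true_mrna_fc": eff.true_mrna_fc,
                "true_protein_fc": eff.true_protein_fc,
                "luc_class": luc_class,
                "toxic_at_assay": toxic,
                "final_candidate": final,
            }
        )
    return pd.DataFrame(rows)


def write_bundle(
    bundle: TriageInputs,
    effects: Sequence[EffectModel],
    noise: NoiseModel,
    outdir: str | Path,
) -> dict[str, str]:
    """Write the full input bundle + truth + manifest to a directory.

    Every CSV records the generator seed in a leading comment line.
    Returns the file map written into the manifest.
    """
    from .plate_model import write_plate_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"seed={noise.seed}"
    files: dict[str, str] = {}

    write_plate_table(bundle.screen, outdir / "screen_plates.csv", header_comment=header)
    files["screen_plates"] = "screen_plates.csv"
    tables = {
        "resazurin": bundle.resazurin,
        "hcs": bundle.hcs,
        "luc_qpcr_a1": bundle.luc_qpcr_a1,
        "luc_qpcr_a6": bundle.luc_qpcr_a6,
        "snca_qpcr_wt": bundle.snca_qpcr_wt,
        "protein_icw": bundle.protein_icw,
        "protein_wb": bundle.protein_wb,
        "truth": truth_table(effects),
    }
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# {header}\n")
            df.to_csv(fh, index=False)
        files[name] = path.name
    manifest = {
        "seed": noise.seed,
        "noise": {
            "well_cv": noise.well_cv,
            "plate_factor_sd": noise.plate_factor_sd,
            "ct_sd": noise.ct_sd,
            "count_n": noise.count_n,
        },
        "n_compounds": len(effects),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = "manifest.json"
    return files
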