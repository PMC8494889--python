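import io
import math

import numpy as np
import pandas as pd
import pytest

from synscreen.hit_calling import HitThreshold, call_hits, normalize_run, HitClass
from synscreen.plate_model import PlateGeometry, WellType
from synscreen.qpcr_quant import relative_expression_table
from synscreen.synthetic_data import (
    DEFAULT_CONCENTRATIONS_UM,
    EffectModel,
    LayoutError,
    NoiseModel,
    generate_ct_table,
    generate_dose_response,
    generate_screen,
    generate_triage_bundle,
    hill_viability,
    make_spiked_effects,
    make_study_effects,
    truth_table,
    write_bundle,
)
from synscreen.triage import toxicity_calls_from_tables


ZERO = dict(well_cv=0.0, plate_factor_sd=0.0, ct_sd=0.0)


class TestEffectModels:
    def test_inert_compounds_cannot_be_toxic(self):
        with pytest.raises(ValueError, match="inert"):
            EffectModel("C1", toxic_ic=5.0)

    def test_specific_compounds_act_only_in_screening_line(self):
        eff = EffectModel("C1", true_luc_fc=1.6, specific=True, true_mrna_fc=1.6)
        assert eff.luc_fc("A1") == 1.6 and eff.luc_fc("A6") == 1.0
        pleio = EffectModel("C2", true_luc_fc=1.6, specific=False, true_mrna_fc=1.6)
        assert pleio.luc_fc("A6") == 1.6

    def test_study_effect_ranges(self):
        effects = make_study_effects(n_compounds=100, seed=0)
        truth = truth_table(effects)
        act = truth[truth.luc_class == "activator"]
        assert ((act.true_luc_fc >= 1.4) & (act.true_luc_fc <= 2.0)).all()
        assert ((act.true_protein_fc >= 1.3) & (act.true_protein_fc <= 2.0)).all()


class TestScreenGeneration:
    def test_zero_noise_inert_library_has_unit_fold_changes_and_no_hits(self):
        effects = [EffectModel(f"C{i}") for i in range(30)]
        run = generate_screen(effects, NoiseModel(seed=1, **ZERO))
        records = normalize_run(run)
        assert all(math.isclose(r.fold_change, 1.0, rel_tol=1e-12) for r in records)
        calls = call_hits(records, HitThreshold(control_sd=0.05, k=4))
        assert all(c.classification is HitClass.INACTIVE for c in calls)

    def test_layout_error_when_control_block_overflows(self):
        effects = [EffectModel(f"C{i}") for i in range(100)]
        with pytest.raises(LayoutError, match="control"):
            generate_screen(
                effects,
                NoiseModel(seed=1),
                n_untreated_controls=30,
                n_vehicle_controls=2,
                n_positive_controls=0,
                geometry=PlateGeometry.W96,
            )

    def test_placements_rerandomized_across_replicates(self):
        effects = make_spiked_effects(n_compounds=300, n_spiked=0)
        run = generate_screen(effects, NoiseModel(seed=3))
        address = {}
        for plate in run.plates:
            for w in plate.wells:
                if w.well_type is WellType.COMPOUND:
                    address.setdefault(w.compound_id, []).append((plate.replicate_index, w.address))
        moved = sum(
            1 for addrs in address.values() if len({a for _, a in addrs}) > 1
        )
        # under uniform re-randomization essentially every compound moves
        assert moved / len(address) > 0.98

    def test_identical_seed_reproduces_byte_identical_files(self, tmp_path):
        effects = make_study_effects(n_compounds=40, seed=6)
        for d in ("one", "two"):
            noise = NoiseModel(seed=6)
            bundle = generate_triage_bundle(effects, noise)
            write_bundle(bundle, effects, noise, tmp_path / d)
        for name in ("screen_plates.csv", "resazurin.csv", "luc_qpcr_a1.csv",
                     "protein_icw.csv", "truth.csv", "manifest.json"):
            assert (tmp_path / "one" / name).read_bytes() == (tmp_path / "two" / name).read_bytes()

    def test_seed_recorded_in_file_headers(self, tmp_path):
        effects = make_study_effects(n_compounds=20, seed=11)
        noise = NoiseModel(seed=11)
        write_bundle(generate_triage_bundle(effects, noise), effects, noise, tmp_path)
        first = (tmp_path / "resazurin.csv").read_text().splitlines()[0]
        assert first == "# seed=11"


class TestDoseResponse:
    def test_hill_midpoint_identity(self):
        eff = EffectModel("C1", true_luc_fc=0.5, toxic_ic=5.0, hill_slope=2.0,
                          true_mrna_fc=0.5, true_protein_fc=0.5)
        assert hill_viability(eff, 5.0) == pytest.approx(0.5)
        assert hill_viability(EffectModel("C2"), 40.0) == 1.0

    def test_noise_free_toxicity_labels_round_trip(self):
        effects = make_study_effects(
            n_compounds=30, n_toxic_inhibitors=8, n_specific_activators=2,
            n_pleiotropic_activators=0, seed=4,
        )
        res, hcs = generate_dose_response(effects, NoiseModel(seed=4, **ZERO))
        calls = toxicity_calls_from_tables(res, hcs, assay_concentration=10.0, threshold=0.70)
        truth = truth_table(effects)
        for _, row in truth.iterrows():
            assert calls[row.compound_id].toxic == row.toxic_at_assay

    def test_hcs_counts_follow_death_probability(self):
        eff = EffectModel("C1", true_luc_fc=0.5, toxic_ic=10.0, hill_slope=2.0,
                          true_mrna_fc=0.5, true_protein_fc=0.5)
        noise = NoiseModel(seed=13, count_n=400)
        _, hcs = generate_dose_response([eff] , noise, concentrations=[10.0] * 1,
                                        n_replicates=1)
        v = hcs.iloc[0]["live"] / (hcs.iloc[0]["live"] + hcs.iloc[0]["dead"])
        # true viability at the midpoint is 0.5; binomial error on ~400 cells
        assert abs(v - 0.5) < 5 * math.sqrt(0.25 / 400)


class TestCtTables:
    def test_log_identity_shifts_target_one_cycle(self):
        eff = EffectModel("C1", true_luc_fc=2.0, true_mrna_fc=2.0, true_protein_fc=2.0)
        df = generate_ct_table([eff], NoiseModel(seed=1, **ZERO), "LUC", ("UBC", "GUSB"))
        target = df[(df.compound_id == "C1") & (df.gene_id == "LUC")]["ct"].unique()
        control = df[(df.compound_id == "DMSO") & (df.gene_id == "LUC")]["ct"].unique()
        assert target == pytest.approx(control - 1.0)

    def test_noise_free_pfaffl_round_trip(self):
        effects = make_study_effects(n_compounds=10, n_specific_activators=3,
                                     n_pleiotropic_activators=0, n_toxic_inhibitors=2,
                                     seed=8)
        df = generate_ct_table(effects, NoiseModel(seed=8, **ZERO), "SNCA",
                               ("UBC", "HPRT1", "GUSB"), line="WT")
        ratios = {r.compound_id: r.ratio
                  for r in relative_expression_table(df, "SNCA", ["UBC", "HPRT1", "GUSB"], "DMSO")}
        for eff in effects:
            assert ratios[eff.compound_id] == pytest.approx(eff.true_mrna_fc, rel=1e-9)

    def test_counter_screen_line_sees_only_pleiotropic_effects(self):
        specific = EffectModel("S", true_luc_fc=1.8, specific=True, true_mrna_fc=1.8)
        pleio = EffectModel("P", true_luc_fc=1.8, specific=False, true_mrna_fc=1.8)
        df = generate_ct_table([specific, pleio], NoiseModel(seed=1, **ZERO),
                               "LUC", ("UBC", "GUSB"), line="A6")
        ratios = {r.compound_id: r.ratio
                  for r in relative_expression_table(df, "LUC", ["UBC", "GUSB"], "DMSO")}
        assert ratios["S"] == pytest.approx(1.0, rel=1e-12)
        assert ratios["P"] == pytest.approx(1.8, rel=1e-9)

    def test_recovery_unbiased_over_seeds(self):
        # triplicates at the default CT noise recover the true ratio on average
        eff = EffectModel("C1", true_luc_fc=1.6, true_mrna_fc=1.6, true_protein_fc=1.6)
        estimates = []
        for seed in range(40):
            df = generate_ct_table([eff], NoiseModel(seed=seed), "SNCA",
                                   ("UBC", "HPRT1", "GUSB"), line="WT")
            (r,) = relative_expression_table(df, "SNCA", ["UBC", "HPRT1", "GUSB"], "DMSO")
            estimates.append(r.ratio)
        assert np.mean(estimates) == pytest.approx(1.6, rel=0.03)
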