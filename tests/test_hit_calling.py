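import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synscreen.hit_calling import (
    ConsensusRule,
    FoldChangeRecord,
    HitClass,
    HitThreshold,
    NormalizationError,
    call_hits,
    estimate_control_sd,
    normalize_plate,
    normalize_run,
    rank_by_potency,
)
from synscreen.plate_model import PlateValidationError, ScreenRun, WellType
from synscreen.synthetic_data import NoiseModel, make_spiked_effects, generate_screen

from conftest import build_plate


def fc_by_compound(records):
    return {
        r.compound_id: r.fold_change
        for r in records
        if r.well_type is WellType.COMPOUND
    }


class TestNormalizePlate:
    def test_uniform_plate_gives_unit_fold_changes(self):
        plate = build_plate({"A": 1000.0, "B": 1000.0}, [1000.0] * 3)
        assert all(r.fold_change == 1.0 for r in normalize_plate(plate))

    def test_forced_arithmetic(self, simple_plate):
        assert fc_by_compound(normalize_plate(simple_plate)) == {"A": 2.0, "B": 0.5}

    def test_control_fold_changes_mean_exactly_one(self):
        rng = np.random.default_rng(11)
        plate = build_plate(
            {"A": 120.0}, list(rng.uniform(80, 120, 22))
        )
        controls = [
            r.fold_change
            for r in normalize_plate(plate)
            if r.well_type is WellType.UNTREATED_CONTROL
        ]
        assert len(controls) == 22
        assert math.isclose(sum(controls) / len(controls), 1.0, rel_tol=1e-12)

    def test_multiplicative_plate_factor_cancels(self):
        base = build_plate({"A": 150.0, "B": 60.0}, [100.0, 90.0, 110.0])
        scaled = build_plate(
            {"A": 150.0 * 1.7, "B": 60.0 * 1.7}, [170.0, 153.0, 187.0]
        )
        a, b = fc_by_compound(normalize_plate(base)), fc_by_compound(normalize_plate(scaled))
        for cid in a:
            assert math.isclose(a[cid], b[cid], rel_tol=1e-12)

    def test_too_few_controls_is_an_error(self):
        plate = build_plate({"A": 1.0}, [1.0, 1.0])
        with pytest.raises(PlateValidationError):
            normalize_plate(plate)

    def test_zero_control_mean_is_degenerate(self):
        plate = build_plate({"A": 1.0}, [0.0, 0.0, 0.0])
        with pytest.raises(NormalizationError, match="degenerate"):
            normalize_plate(plate)


class TestThreshold:
    def test_printed_cutoff_from_control_sd(self):
        thr = HitThreshold(control_sd=0.0825, k=4)
        assert thr.offset == pytest.approx(0.33, abs=1e-12)
        assert thr.lower_bound == pytest.approx(0.67, abs=1e-12)
        assert thr.upper_bound == pytest.approx(1.33, abs=1e-12)

    def test_identical_controls_collapse_band_with_warning(self, caplog):
        recs = [
            FoldChangeRecord(None, 1, "P1", 1.0, WellType.UNTREATED_CONTROL)
            for _ in range(5)
        ]
        with caplog.at_level("WARNING", logger="synscreen.hit_calling"):
            thr = estimate_control_sd(recs)
        assert thr.control_sd == 0.0
        assert (thr.lower_bound, thr.upper_bound) == (1.0, 1.0)
        assert any("degenerate threshold" in m for m in caplog.messages)

    def test_sd_recovered_from_simulated_controls(self):
        rng = np.random.default_rng(42)
        true_sd = 0.08
        recs = [
            FoldChangeRecord(None, 1, "P1", fc, WellType.UNTREATED_CONTROL)
            for fc in rng.normal(1.0, true_sd, 1000)
        ]
        thr = estimate_control_sd(recs)
        assert abs(thr.control_sd - true_sd) / true_sd < 0.10

    def test_fewer_than_two_values_is_an_error(self):
        rec = FoldChangeRecord(None, 1, "P1", 1.0, WellType.UNTREATED_CONTROL)
        with pytest.raises(NormalizationError, match=">= 2"):
            estimate_control_sd([rec])

    def test_lower_bound_must_stay_positive(self):
        with pytest.raises(ValueError, match="not positive"):
            HitThreshold(control_sd=0.3, k=4)

    @given(
        sd=st.floats(0.0, 0.2),
        k=st.floats(0.1, 4.0),
        delta=st.floats(0.01, 2.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_bounds_monotone_in_k_and_sd(self, sd, k, delta):
        thr = HitThreshold(control_sd=sd, k=k)
        wider = HitThreshold(control_sd=sd, k=k + min(delta, (0.99 - k * sd) / max(sd, 1e-9)))
        assert wider.upper_bound >= thr.upper_bound
        assert wider.lower_bound <= thr.lower_bound


class TestCallHits:
    def make_records(self, fcs_by_compound):
        return [
            FoldChangeRecord(cid, rep + 1, "P1", fc)
            for cid, fcs in fcs_by_compound.items()
            for rep, fc in enumerate(fcs)
        ]

    def test_activator_above_band(self):
        thr = HitThreshold(control_sd=0.0825, k=4)
        (call,) = call_hits(self.make_records({"C1": [1.40]}), thr)
        assert call.classification is HitClass.ACTIVATOR

    def test_boundary_value_is_inactive(self):
        thr = HitThreshold(control_sd=0.0825, k=4)
        (call,) = call_hits(self.make_records({"C1": [thr.upper_bound]}), thr)
        assert call.classification is HitClass.INACTIVE

    def test_classification_partitions_compounds(self):
        thr = HitThreshold(control_sd=0.05, k=4)
        calls = call_hits(
            self.make_records({"a": [1.5], "b": [0.5], "c": [1.0], "d": [1.1]}), thr
        )
        assert len(calls) == 4
        by_class = {c: 0 for c in HitClass}
        for call in calls:
            by_class[call.classification] += 1
        assert sum(by_class.values()) == 4
        assert by_class[HitClass.ACTIVATOR] == 1
        assert by_class[HitClass.INHIBITOR] == 1

    def test_zero_k_limit_flags_every_non_unit_compound(self):
        thr = HitThreshold(control_sd=0.05, k=1e-12)
        calls = call_hits(self.make_records({"a": [1.001], "b": [0.999], "c": [1.0]}), thr)
        classes = {c.compound_id: c.classification for c in calls}
        assert classes["a"] is HitClass.ACTIVATOR
        assert classes["b"] is HitClass.INHIBITOR
        assert classes["c"] is HitClass.INACTIVE

    @pytest.mark.parametrize(
        "rule,expected",
        [
            (ConsensusRule.MEAN, HitClass.ACTIVATOR),  # mean 1.40 > 1.33
            (ConsensusRule.MAJORITY, HitClass.ACTIVATOR),  # 2 of 3 beyond
            (ConsensusRule.ALL, HitClass.INACTIVE),  # one replicate inside
        ],
    )
    def test_consensus_rules(self, rule, expected):
        thr = HitThreshold(control_sd=0.0825, k=4)
        (call,) = call_hits(self.make_records({"C1": [1.50, 1.40, 1.30]}), thr, rule)
        assert call.classification is expected

    def test_potency_ranking_orders_by_distance_from_unit(self):
        thr = HitThreshold(control_sd=0.05, k=4)
        calls = call_hits(self.make_records({"a": [1.3], "b": [0.5], "c": [1.6]}), thr)
        assert [c.compound_id for c in rank_by_potency(calls)] == ["c", "b", "a"]


class TestOperatingCharacteristics:
    def test_spiked_activators_recovered_on_noisy_screen(self):
        effects = make_spiked_effects(n_compounds=500, n_spiked=20, spiked_fc=1.6)
        spiked = {e.compound_id for e in effects if e.true_luc_fc != 1.0}
        run = generate_screen(effects, NoiseModel(seed=77, well_cv=0.05))
        records = normalize_run(run)
        calls = call_hits(records, estimate_control_sd(records))
        hits = {c.compound_id for c in calls if c.classification is HitClass.ACTIVATOR}
        assert len(spiked & hits) >= 19
        # 4-SD band: essentially no inert compound should cross it
        assert len(hits - spiked) <= 2

    def test_noise_free_screen_matches_ground_truth_labels(self):
        effects = make_spiked_effects(n_compounds=100, n_spiked=5, spiked_fc=1.6)
        run = generate_screen(
            effects, NoiseModel(seed=1, well_cv=0.0, plate_factor_sd=0.0)
        )
        records = normalize_run(run)
        calls = call_hits(records, HitThreshold(control_sd=0.0825, k=4))
        for call in calls:
            truth = next(e for e in effects if e.compound_id == call.compound_id)
            expected = HitClass.ACTIVATOR if truth.true_luc_fc > 1.33 else HitClass.INACTIVE
            assert call.classification is expected
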