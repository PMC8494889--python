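import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synscreen.qpcr_quant import (
    QpcrError,
    delta_ct,
    per_sample_ratios,
    pfaffl_ratio,
    relative_expression_table,
)

# direct arbitrary-precision evaluation of
# 1.9^2 / sqrt(2.0^0.5 * 1.8^-0.5), frozen from sympy
PFAFFL_ORACLE = 3.5161535245953213


class TestDeltaCt:
    def test_earlier_amplification_is_positive(self):
        assert delta_ct(25.0, 24.0) == 1.0
        assert delta_ct(24.0, 24.0) == 0.0

    @given(a=st.floats(10, 35), b=st.floats(10, 35))
    @settings(deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert delta_ct(a, b) == -delta_ct(b, a)


class TestPfafflRatio:
    def test_no_change_gives_unit_ratio(self):
        assert pfaffl_ratio(0.0, [0.0, 0.0]) == 1.0

    def test_one_cycle_shift_doubles(self):
        assert pfaffl_ratio(1.0, [0.0, 0.0]) == pytest.approx(2.0, rel=1e-15)

    def test_mixed_efficiencies_match_direct_evaluation(self):
        got = pfaffl_ratio(
            2.0, [0.5, -0.5], target_efficiency=1.9, reference_efficiencies=[2.0, 1.8]
        )
        assert got == pytest.approx(PFAFFL_ORACLE, rel=1e-12)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(QpcrError, match="efficiency"):
            pfaffl_ratio(1.0, [0.0], target_efficiency=1.0)
        with pytest.raises(QpcrError):
            pfaffl_ratio(1.0, [0.0], reference_efficiencies=[2.5])

    @given(
        dct=st.floats(-5, 5),
        refs=st.lists(st.floats(-5, 5), min_size=2, max_size=4),
    )
    @settings(deadline=None, derandomize=True)
    def test_reference_permutation_invariance(self, dct, refs):
        base = pfaffl_ratio(dct, refs)
        for perm in itertools.islice(itertools.permutations(refs), 6):
            assert pfaffl_ratio(dct, list(perm)) == pytest.approx(base, rel=1e-12)

    @given(dct=st.floats(-5, 5), ref=st.floats(-5, 5), eps=st.floats(0.01, 1.0))
    @settings(deadline=None, derandomize=True)
    def test_strict_monotonicity(self, dct, ref, eps):
        base = pfaffl_ratio(dct, [ref])
        assert pfaffl_ratio(dct + eps, [ref]) > base  # increasing in target dCT
        assert pfaffl_ratio(dct, [ref + eps]) < base  # decreasing in reference dCT

    def test_single_reference_equals_livak(self):
        # closed-form equivalence: E = 2 everywhere -> 2^(-ddCT)
        rng = np.random.default_rng(9)
        for _ in range(200):
            ct_t_ctrl, ct_t_trt, ct_r_ctrl, ct_r_trt = rng.uniform(15, 30, 4)
            ddct = (ct_t_trt - ct_r_trt) - (ct_t_ctrl - ct_r_ctrl)
            got = pfaffl_ratio(
                delta_ct(ct_t_ctrl, ct_t_trt), [delta_ct(ct_r_ctrl, ct_r_trt)]
            )
            assert got == pytest.approx(2.0 ** (-ddct), rel=1e-12)


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "compound_id", "condition", "gene_id", "ct"])


def make_rows(cid, condition, cts: dict[str, float], sample="s1"):
    return [
        {"sample_id": sample, "compound_id": cid, "condition": condition, "gene_id": g, "ct": ct}
        for g, ct in cts.items()
    ]


class TestRelativeExpressionTable:
    def test_identical_conditions_give_unit_ratios(self):
        cts = {"SNCA": 24.0, "UBC": 20.0, "GUSB": 25.0}
        df = ct_table(
            make_rows("DMSO", "control", cts, "c1")
            + make_rows("DMSO", "control", cts, "c2")
            + make_rows("C1", "treated", cts, "t1")
        )
        (r,) = relative_expression_table(df, "SNCA", ["UBC", "GUSB"], "control")
        assert r.ratio == pytest.approx(1.0, rel=1e-12)

    def test_known_fold_change_recovered(self):
        # treated target amplifies 1 cycle earlier with E=2 -> ratio 2
        ctrl = {"SNCA": 24.0, "UBC": 20.0}
        trt = {"SNCA": 23.0, "UBC": 20.0}
        df = ct_table(
            make_rows("DMSO", "control", ctrl, "c1")
            + make_rows("C1", "treated", trt, "t1")
        )
        (r,) = relative_expression_table(df, "SNCA", ["UBC"], "control")
        assert r.ratio == pytest.approx(2.0, rel=1e-12)

    def test_technical_replicates_aggregated_on_ct_scale(self):
        ctrl = {"SNCA": 24.0, "UBC": 20.0}
        df = ct_table(
            make_rows("DMSO", "control", ctrl, "c1")
            + make_rows("C1", "treated", {"SNCA": 22.0, "UBC": 20.0}, "t1")
            + make_rows("C1", "treated", {"SNCA": 24.0, "UBC": 20.0}, "t2")
        )
        (r,) = relative_expression_table(df, "SNCA", ["UBC"], "control")
        # mean CT 23 -> one cycle early -> ratio 2 (not mean of 4 and 1)
        assert r.ratio == pytest.approx(2.0, rel=1e-12)

    def test_missing_gene_names_the_gap(self):
        df = ct_table(
            make_rows("DMSO", "control", {"SNCA": 24.0, "UBC": 20.0}, "c1")
            + make_rows("C1", "treated", {"SNCA": 23.0}, "t1")
        )
        with pytest.raises(QpcrError, match="UBC.*C1|C1.*UBC"):
            relative_expression_table(df, "SNCA", ["UBC"], "control")

    def test_global_ct_shift_leaves_ratios_unchanged(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(3):
            rows += make_rows("DMSO", "control",
                              {g: float(rng.uniform(18, 28)) for g in ("T", "R1", "R2")},
                              f"c{s}")
            rows += make_rows("C1", "treated",
                              {g: float(rng.uniform(18, 28)) for g in ("T", "R1", "R2")},
                              f"t{s}")
        df = ct_table(rows)
        shifted = df.assign(ct=df["ct"] + 3.7)
        (a,) = relative_expression_table(df, "T", ["R1", "R2"], "control")
        (b,) = relative_expression_table(shifted, "T", ["R1", "R2"], "control")
        assert b.ratio == pytest.approx(a.ratio, rel=1e-12)


def test_per_sample_ratios_include_scattering_controls():
    rows = (
        make_rows("DMSO", "control", {"T": 24.0, "R": 20.0}, "c1")
        + make_rows("DMSO", "control", {"T": 24.4, "R": 20.0}, "c2")
        + make_rows("C1", "treated", {"T": 23.0, "R": 20.0}, "t1")
    )
    out = per_sample_ratios(ct_table(rows), "T", ["R"], "control")
    assert set(out["sample_id"]) == {"c1", "c2", "t1"}
    controls = out[out["compound_id"] == "control"]["ratio"]
    # control samples scatter around 1 (geometric mean exactly 1)
    assert np.exp(np.log(controls).mean()) == pytest.approx(1.0, rel=1e-12)
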