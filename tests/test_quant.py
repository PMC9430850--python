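import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ntcascan.quant import (
    PeptideTable,
    SpectroParams,
    hi3_amount,
    hi3_table,
    normalize_total_abundance,
    og_amount,
    pe_concentration,
    pfaffl_from_table,
    pfaffl_ratio,
    ratio_from_signed_fold,
    signed_fold,
    welch_p,
)


class TestPfaffl:
    def test_equal_deltas_give_unity(self):
        assert pfaffl_ratio(20, 17, 18, 15, 2.0, 2.0) == pytest.approx(1.0)

    def test_pure_target_shift_at_full_efficiency(self):
        assert pfaffl_ratio(20, 17, 18, 18, 2.0, 2.0) == pytest.approx(8.0)

    def test_mixed_efficiencies(self):
        # direct evaluation of the formula: 1.9^2 / 2.0^1 = 1.805
        assert pfaffl_ratio(22, 20, 19, 18, 1.9, 2.0) == pytest.approx(1.805)

    @pytest.mark.parametrize("eff", [1.0, 0.9, 2.1, 0.0])
    def test_efficiency_outside_interval_rejected(self, eff):
        with pytest.raises(ValueError):
            pfaffl_ratio(20, 19, 18, 18, eff, 2.0)

    @given(st.floats(min_value=-3, max_value=3), st.floats(min_value=0.1, max_value=1))
    def test_monotone_in_target_delta_ct(self, delta, step):
        lo = pfaffl_ratio(20 + delta, 20, 18, 18, 1.9, 1.9)
        hi = pfaffl_ratio(20 + delta + step, 20, 18, 18, 1.9, 1.9)
        assert hi > lo

    @given(st.floats(min_value=-3, max_value=3), st.floats(min_value=0.1, max_value=1))
    def test_antitone_in_reference_delta_ct(self, delta, step):
        lo = pfaffl_ratio(20, 20, 18 + delta, 18, 1.9, 1.9)
        hi = pfaffl_ratio(20, 20, 18 + delta + step, 18, 1.9, 1.9)
        assert hi < lo


class TestSignedFold:
    @pytest.mark.parametrize("ratio,fold", [(0.25, -4.0), (1.0, 1.0), (2.0, 2.0)])
    def test_examples(self, ratio, fold):
        assert signed_fold(ratio) == pytest.approx(fold)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            signed_fold(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_round_trip(self, ratio):
        assert ratio_from_signed_fold(signed_fold(ratio)) == pytest.approx(ratio)


def make_table(rows, standard_id="STD", standard_amount=50.0):
    df = pd.DataFrame(rows, columns=["protein_id", "peptide_id", "intensity", "unique"])
    return PeptideTable(df=df, standard_id=standard_id, standard_amount=standard_amount)


@pytest.fixture
def basic_table():
    rows = [("STD", f"s{i}", 1000.0, True) for i in range(3)]
    rows += [("P1", f"p{i}", 1000.0, True) for i in range(3)]
    rows += [("P2", f"q{i}", 2000.0, True) for i in range(4)]
    rows += [("P3", "r0", 500.0, True), ("P3", "r1", 700.0, True)]
    rows += [("P4", "u0", 900.0, True), ("P4", "u1", 900.0, False)]
    return make_table(rows)


class TestHi3:
    def test_protein_matching_standard_gets_spike_amount(self, basic_table):
        assert hi3_amount(basic_table, "P1") == pytest.approx(50.0)

    def test_proportional_to_intensity(self, basic_table):
        assert hi3_amount(basic_table, "P2") == pytest.approx(100.0)

    def test_two_peptides_allowed_with_warning(self, basic_table):
        with pytest.warns(UserWarning, match="two unique peptides"):
            amount = hi3_amount(basic_table, "P3")
        assert amount == pytest.approx(600.0 / 1000.0 * 50.0)

    def test_single_unique_peptide_rejected_by_name(self, basic_table):
        with pytest.raises(ValueError, match="P4"):
            hi3_amount(basic_table, "P4")

    def test_missing_standard_rejected(self):
        with pytest.raises(ValueError, match="standard"):
            make_table([("P1", "p0", 1.0, True)], standard_id="STD")

    def test_top3_of_many_peptides(self):
        rows = [("STD", f"s{i}", 100.0, True) for i in range(3)]
        rows += [("P", f"p{i}", v, True) for i, v in enumerate([10, 400, 300, 200, 50])]
        # top 3 are 400, 300, 200 -> mean 300
        assert hi3_amount(make_table(rows), "P") == pytest.approx(150.0)

    def test_scale_equivariance(self, basic_table):
        base = hi3_amount(basic_table, "P2")
        df = basic_table.df.copy()
        df.loc[df.protein_id == "P2", "intensity"] *= 3
        scaled = make_table(df.values.tolist())
        assert hi3_amount(scaled, "P2") == pytest.approx(3 * base)
        df_all = basic_table.df.copy()
        df_all["intensity"] *= 7
        assert hi3_amount(make_table(df_all.values.tolist()), "P2") == pytest.approx(base)

    def test_table_excludes_underquantified_proteins(self, basic_table):
        result = hi3_table(basic_table)
        assert set(result.protein_id) == {"STD", "P1", "P2", "P3"}


class TestNormalizeTotalAbundance:
    def test_reported_scale_factors(self):
        amounts = pd.DataFrame({"s1": [60.0, 40.0], "s2": [200.0, 100.0]})
        out = normalize_total_abundance(amounts)
        # totals 100 and 300 -> factors 2.0 and 2/3
        assert out["s1"].tolist() == pytest.approx([120.0, 80.0])
        assert out["s2"].tolist() == pytest.approx([400.0 / 3, 200.0 / 3])

    def test_equal_totals_identity(self):
        amounts = pd.DataFrame({"s1": [60.0, 40.0], "s2": [10.0, 90.0]})
        out = normalize_total_abundance(amounts)
        pd.testing.assert_frame_equal(out, amounts)

    def test_random_table_totals_equalized(self):
        rng = np.random.default_rng(3)
        amounts = pd.DataFrame(rng.uniform(1, 100, size=(20, 4)))
        totals = normalize_total_abundance(amounts).sum(axis=0)
        assert np.allclose(totals, totals.iloc[0])

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_total_abundance(pd.DataFrame({"s1": [1.0], "s2": [0.0]}))


class TestSpectrophotometry:
    def test_pe_at_unit_path(self):
        assert pe_concentration(2.15) == pytest.approx(1.0e-6)
        assert pe_concentration(0.215) == pytest.approx(1.0e-7)
        assert pe_concentration(0.0) == 0.0

    def test_pe_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            pe_concentration(-0.1)

    def test_og_hand_evaluated_example(self):
        # delta A 0.0622 / 6220 * 1 mL -> 10 nmol in 1 mg protein
        assert og_amount(0.0622, 1e-3, 1.0) == pytest.approx(10.0)

    def test_og_zero_and_volume_linearity(self):
        assert og_amount(0.0, 1e-3, 1.0) == 0.0
        assert og_amount(0.0622, 2e-3, 1.0) == pytest.approx(20.0)

    def test_og_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            og_amount(0.1, 1e-3, 0.0)

    @pytest.mark.parametrize("a", [0.0, 0.1, 0.5, 1.0, 2.0])
    def test_linearity_in_absorbance(self, a):
        params = SpectroParams()
        assert pe_concentration(2 * a, params) == pytest.approx(
            2 * pe_concentration(a, params)
        )
        assert og_amount(2 * a, 1e-3, 1.0, params) == pytest.approx(
            2 * og_amount(a, 1e-3, 1.0, params)
        )


class TestTableHelpers:
    def test_pfaffl_from_table_recovers_planted_ratio(self):
        rows = []
        for rep in (1, 2, 3):
            rows += [
                ("rnpB", "control", rep, 18.0, 2.0),
                ("rnpB", "sample", rep, 18.0, 2.0),
                ("nirA", "control", rep, 20.0, 2.0),
                ("nirA", "sample", rep, 17.0, 2.0),
            ]
        ct = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct", "efficiency"])
        out = pfaffl_from_table(ct, ref_gene="rnpB")
        assert out.ratio.iloc[0] == pytest.approx(8.0)
        assert out.signed_fold.iloc[0] == pytest.approx(8.0)

    def test_missing_reference_gene_rejected(self):
        ct = pd.DataFrame(
            [("g", "control", 1, 20.0, 2.0)],
            columns=["gene", "condition", "replicate", "ct", "efficiency"],
        )
        with pytest.raises(ValueError, match="reference"):
            pfaffl_from_table(ct, ref_gene="rnpB")

    def test_welch_p_symmetric_groups(self):
        assert welch_p([1.0, 1.1, 0.9], [1.0, 1.1, 0.9]) == pytest.approx(1.0)
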