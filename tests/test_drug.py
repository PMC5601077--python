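"""Hill pore-block model, composition with cell scalings, compound tables."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from aptrial.cell_engine import IonicScaling
from aptrial.drug import (
    ChannelBlock, CompoundRecord, ConcentrationSpec, apply_block,
    ic50_from_single_point, read_compound_table, remaining_fraction,
    write_compound_table,
)


class TestRemainingFraction:
    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0, 3.7])
    def test_half_block_at_ic50_for_any_hill(self, hill):
        assert remaining_fraction(2.5, 2.5, hill) == pytest.approx(0.5)

    def test_no_drug_no_block(self):
        assert remaining_fraction(0.0, 1.0, 2.0) == 1.0

    def test_tenfold_ic50_first_order(self):
        assert remaining_fraction(10.0, 1.0, 1.0) == pytest.approx(1 / 11)

    @pytest.mark.parametrize("kwargs", [
        dict(d_um=-1.0, ic50_um=1.0, hill=1.0),
        dict(d_um=1.0, ic50_um=0.0, hill=1.0),
        dict(d_um=1.0, ic50_um=1.0, hill=0.0),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            remaining_fraction(**kwargs)

    @given(ic50=st.floats(0.01, 100), hill=st.floats(0.2, 4),
           d_lo=st.floats(0.01, 1000), factor=st.floats(1.001, 10))
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_concentration(self, ic50, hill, d_lo, factor):
        # restrict to block fractions large enough to be representable;
        # below ~1e-12 the fractions round to the same float
        assume((d_lo / ic50) ** hill > 1e-9)
        assert remaining_fraction(d_lo * factor, ic50, hill) \
            < remaining_fraction(d_lo, ic50, hill)

    @given(ic50=st.floats(0.1, 10), hill=st.floats(0.2, 3),
           delta=st.floats(0.1, 2))
    @settings(max_examples=100, deadline=None)
    def test_hill_steepens_around_ic50(self, ic50, hill, delta):
        # above the IC50 a larger h blocks more; below it, less
        above = ic50 * (1 + delta)
        below = ic50 / (1 + delta)
        assert remaining_fraction(above, ic50, hill + 0.5) \
            < remaining_fraction(above, ic50, hill)
        assert remaining_fraction(below, ic50, hill + 0.5) \
            > remaining_fraction(below, ic50, hill)


class TestIC50FromSinglePoint:
    def test_half_block_returns_tested_concentration(self):
        assert ic50_from_single_point(3.7, 0.5) == pytest.approx(3.7)

    def test_ninety_percent_block(self):
        assert ic50_from_single_point(1.0, 0.9) == pytest.approx(1 / 9)

    @given(d_max=st.floats(0.01, 100), blocked=st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, d_max, blocked):
        ic50 = ic50_from_single_point(d_max, blocked)
        assert remaining_fraction(d_max, ic50, 1.0) \
            == pytest.approx(1.0 - blocked, rel=1e-9)

    @pytest.mark.parametrize("blocked", [0.0, 1.0, -0.2, 1.3])
    def test_uninformative_block_rejected(self, blocked):
        with pytest.raises(ValueError):
            ic50_from_single_point(1.0, blocked)


class TestApplyBlock:
    @pytest.fixture
    def ikr_blocker(self):
        return CompoundRecord("blocker", "I",
                              (ChannelBlock("I_Kr", ic50_um=1.0),), 0.1, "1")

    def test_zero_concentration_unchanged(self, ikr_blocker):
        scaling = IonicScaling(g_Kr=0.8)
        assert apply_block(scaling, ikr_blocker, 0.0) == scaling

    def test_ic50_halves_target_channel(self, ikr_blocker):
        blocked = apply_block(IonicScaling.baseline(), ikr_blocker, 1.0)
        assert blocked.g_Kr == pytest.approx(0.5)
        assert all(getattr(blocked, n) == 1.0 for n in
                   ("g_Na", "g_NaL", "g_to", "g_Ks", "g_K1", "g_NCX",
                    "g_NaK", "g_CaL"))

    def test_multiplicative_composition_with_population_scaling(self, ikr_blocker):
        blocked = apply_block(IonicScaling(g_Kr=0.8), ikr_blocker, 1.0)
        assert blocked.g_Kr == pytest.approx(0.4)

    @given(d=st.floats(0, 1000),
           channels=st.sets(st.sampled_from(
               ["I_Na", "I_NaL", "I_to", "I_Kr", "I_Ks", "I_K1", "I_CaL"]),
               min_size=1, max_size=7))
    @settings(max_examples=100, deadline=None)
    def test_pump_and_exchanger_never_touched(self, d, channels):
        compound = CompoundRecord(
            "multi", "I",
            tuple(ChannelBlock(c, ic50_um=0.5) for c in sorted(channels)),
            1.0, "0")
        scaling = IonicScaling(g_NCX=1.7, g_NaK=0.3)
        blocked = apply_block(scaling, compound, d)
        assert blocked.g_NCX == 1.7 and blocked.g_NaK == 0.3


class TestCompoundRecord:
    def test_nc_category_maps_to_zero(self):
        record = CompoundRecord("Verapamil", "II", (), 0.081, "NC")
        assert record.truth_category == 0
        assert record.tdp_category == "NC"  # audit value preserved

    def test_duplicate_channel_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CompoundRecord("x", "I",
                           (ChannelBlock("I_Kr", 1.0), ChannelBlock("I_Kr", 2.0)),
                           1.0, "0")

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="I_funny"):
            ChannelBlock("I_funny", 1.0)


class TestConcentrationSpec:
    def test_default_grid(self):
        assert ConcentrationSpec().multiples == (1.0, 10.0, 30.0, 100.0)

    def test_doses_scale_with_eftpc(self):
        spec = ConcentrationSpec(multiples=(1, 10))
        assert spec.doses(0.5) == [(1.0, 0.5), (10.0, 5.0)]

    def test_absolute_dialect(self):
        spec = ConcentrationSpec(multiples=None, absolute_um=(0.1, 1.0))
        assert spec.doses(0.1) == [(1.0, 0.1), (10.0, 1.0)]

    @pytest.mark.parametrize("multiples", [(), (0.0, 1.0), (10.0, 1.0),
                                           (1.0, 1.0)])
    def test_invalid_grids_rejected(self, multiples):
        with pytest.raises(ValueError):
            ConcentrationSpec(multiples=multiples)


class TestCompoundTable:
    def test_bundled_reference_table(self, compound_records):
        """The bundled 15-compound table mirrors the printed clinical risk
        categories (Dofetilide known risk, Ranolazine conditional,
        Verapamil reviewed-but-unclassified -> 0)."""
        assert len(compound_records) == 15
        by_name = {r.name: r for r in compound_records}
        assert by_name["Dofetilide"].truth_category == 1
        assert by_name["Ranolazine"].truth_category == 3
        assert by_name["Verapamil"].tdp_category == "NC"
        assert by_name["Verapamil"].truth_category == 0
        assert by_name["Bepridil"].truth_category == 1
        risky = sum(r.truth_category in {1, 2, 3} for r in compound_records)
        assert risky == 7  # 6 known-risk + Ranolazine

    def test_single_channel_compound(self, compound_records):
        sparflox = [r for r in compound_records if r.name == "Sparfloxacin"][0]
        assert len(sparflox.blocks) == 1
        assert sparflox.blocks[0].channel == "I_Kr"

    def test_round_trip(self, compound_records, tmp_path):
        path = tmp_path / "compounds.csv"
        write_compound_table(compound_records, path)
        assert read_compound_table(path) == compound_records

    def test_unknown_channel_in_file(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "compound,source_id,channel,ic50_uM,hill,eftpc_max_uM,tdp_category\n"
            "X,I,I_funny,1.0,1.0,1.0,0\n")
        with pytest.raises(ValueError, match="I_funny"):
            read_compound_table(path)

    def test_duplicate_row_named(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "compound,source_id,channel,ic50_uM,hill,eftpc_max_uM,tdp_category\n"
            "X,I,I_Kr,1.0,1.0,1.0,0\nX,I,I_Kr,2.0,1.0,1.0,0\n")
        with pytest.raises(ValueError, match="I_Kr"):
            read_compound_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("compound,channel,ic50_uM\nX,I_Kr,1.0\n")
        with pytest.raises(ValueError, match="source_id"):
            read_compound_table(path)
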