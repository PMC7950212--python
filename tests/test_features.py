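"""Unit and property tests for the peptide featurization engine."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ciffrac import features as ft
from conftest import random_peptides
from oracles import (
    oracle_feature_vector,
    oracle_instability_index,
    oracle_isoelectric_point,
    oracle_net_charge,
)

peptide_strategy = st.text(alphabet=ft.AMINO_ACIDS, min_size=2, max_size=40)


class TestValidation:
    @pytest.mark.parametrize("seq,bad,pos", [("ACBD", "B", 3), ("XAA", "X", 1),
                                             ("PEPTIDEZ", "Z", 8), ("ac", "a", 1)])
    def test_invalid_residue_names_offender_and_position(self, seq, bad, pos):
        with pytest.raises(ft.InvalidResidueError) as err:
            ft.validate_sequence(seq)
        assert repr(bad) in str(err.value) and f"position {pos}" in str(err.value)

    def test_length_one_rejected_by_instability_and_featurize(self):
        with pytest.raises(ValueError):
            ft.instability_index("G")
        with pytest.raises(ValueError):
            ft.featurize("G")


class TestAliphaticIndex:
    @pytest.mark.parametrize("seq,expected", [
        ("GGGG", 0.0),        # no A/V/I/L
        ("AAAA", 100.0),      # X_Ala = 100
        ("VV", 290.0),        # 2.9 coefficient on valine
        ("IL", 390.0),        # 3.9 * (X_Ile + X_Leu) = 3.9 * (50 + 50)
    ])
    def test_hand_values(self, seq, expected):
        assert ft.aliphatic_index(seq) == pytest.approx(expected, abs=1e-12)

    @given(peptide_strategy)
    def test_invariant_to_residue_order(self, seq):
        assert ft.aliphatic_index(seq) == pytest.approx(
            ft.aliphatic_index(seq[::-1]), abs=1e-9
        )


class TestNetCharge:
    def test_termini_asymptotes(self):
        # at very low pH only the fully protonated states remain
        assert ft.net_charge("GG", 1e-9 + 0.001) == pytest.approx(1.0, abs=0.01)
        assert ft.net_charge("GG", 13.999) == pytest.approx(-1.0, abs=0.01)
        assert ft.net_charge("K", 0.001) == pytest.approx(2.0, abs=0.01)

    def test_matches_per_group_oracle_at_ph7(self, peptides_50):
        for seq in peptides_50:
            assert ft.net_charge(seq, 7.0) == pytest.approx(
                oracle_net_charge(seq, 7.0), abs=1e-9
            )

    @given(peptide_strategy)
    def test_strictly_decreasing_in_ph(self, seq):
        grid = np.linspace(0.5, 13.5, 27)
        charges = [ft.net_charge(seq, p) for p in grid]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_rejects_out_of_range_ph(self):
        with pytest.raises(ValueError):
            ft.net_charge("GG", 0.0)
        with pytest.raises(ValueError):
            ft.net_charge("GG", 14.5)


class TestIsoelectricPoint:
    def test_glycine_closed_form(self):
        # two ionizable groups: pI = (pKa_Nterm + pKa_Cterm) / 2
        expected = (ft.LEHNINGER.n_term + ft.LEHNINGER.c_term) / 2.0
        assert ft.isoelectric_point("G") == pytest.approx(expected, abs=1e-6)

    def test_pi_is_charge_root(self, peptides_50):
        for seq in peptides_50:
            assert abs(ft.net_charge(seq, ft.isoelectric_point(seq))) < 1e-4

    def test_matches_independent_root_finder(self, peptides_50):
        for seq in peptides_50[:20]:
            assert ft.isoelectric_point(seq) == pytest.approx(
                oracle_isoelectric_point(seq), abs=1e-9
            )

    def test_basic_composition_raises_pi(self):
        assert ft.isoelectric_point("KKKKKK") > ft.isoelectric_point("DDDDDD")


class TestInstabilityIndex:
    @pytest.mark.parametrize("seq", ["GW", "AK", "WP", "MC"])
    def test_dipeptide_reduces_to_five_times_weight(self, seq):
        assert ft.instability_index(seq) == pytest.approx(
            5.0 * ft.DIWV[seq[0]][seq[1]], abs=1e-12
        )

    def test_tripeptide_formula(self):
        expected = (10.0 / 3.0) * (ft.DIWV["G"]["G"] + ft.DIWV["G"]["G"])
        assert ft.instability_index("GGG") == pytest.approx(expected, abs=1e-12)

    def test_matches_published_matrix_oracle(self):
        for seq in random_peptides(20, seed=7):
            assert ft.instability_index(seq) == pytest.approx(
                oracle_instability_index(seq), abs=1e-9
            )

    def test_order_sensitivity(self):
        # unlike the other properties, II depends on residue adjacency
        pairs = [(a, b) for a in ft.AMINO_ACIDS for b in ft.AMINO_ACIDS
                 if ft.DIWV[a][b] != ft.DIWV[b][a]]
        a, b = pairs[0]
        assert ft.instability_index(a + b) != ft.instability_index(b + a)


class TestHydrophobicity:
    def test_kyte_doolittle_mean(self):
        assert ft.hydrophobicity("AIL") == pytest.approx((1.8 + 4.5 + 3.8) / 3)

    def test_homopolymer_equals_scale_value(self):
        assert ft.hydrophobicity("AAAA") == pytest.approx(ft.KYTE_DOOLITTLE["A"])

    @given(peptide_strategy)
    def test_reversal_invariance(self, seq):
        assert ft.hydrophobicity(seq) == pytest.approx(
            ft.hydrophobicity(seq[::-1]), abs=1e-9
        )


class TestComposition:
    def test_acidic_tally(self):
        comp = ft.aa_composition("ACDE")
        assert comp["Acidic No."] == 2 and comp["Acidic mole %"] == pytest.approx(50.0)

    def test_absent_class_is_zero(self):
        comp = ft.aa_composition("GGGG")
        assert comp["Basic No."] == 0 and comp["Basic mole %"] == 0.0

    def test_nonpolar_polar_partition_the_alphabet(self):
        nonpolar = ft.DEFAULT_AA_CLASSES["Nonpolar"]
        polar = ft.DEFAULT_AA_CLASSES["Polar"]
        assert nonpolar | polar == set(ft.AMINO_ACIDS) and not nonpolar & polar
        for seq in random_peptides(10, seed=3):
            comp = ft.aa_composition(seq)
            assert comp["Nonpolar No."] + comp["Polar No."] == len(seq)

    @given(peptide_strategy)
    def test_counts_and_percent_bounds(self, seq):
        comp = ft.aa_composition(seq)
        for cls in ft.CLASS_ORDER:
            count = comp[f"{cls} No."]
            pct = comp[f"{cls} mole %"]
            assert count == int(count) and 0 <= count <= len(seq)
            assert 0.0 <= pct <= 100.0
            assert pct == pytest.approx(100.0 * count / len(seq))


class TestFeaturize:
    def test_emits_23_canonically_ordered_entries(self):
        vec = ft.featurize("ACDEFGHIKLMNPQRSTVWY")
        assert len(vec) == 23
        assert list(vec.index) == list(ft.FEATURE_NAMES)

    def test_pure_function(self):
        a = ft.featurize("PEPTIDEK")
        b = ft.featurize("PEPTIDEK")
        pd.testing.assert_series_equal(a, b)

    def test_entries_match_standalone_operations(self, peptides_50):
        for seq in peptides_50[:10]:
            vec = ft.featurize(seq)
            assert vec["a-Index"] == pytest.approx(ft.aliphatic_index(seq), abs=1e-12)
            assert vec["Charge"] == pytest.approx(ft.net_charge(seq, 7.0), abs=1e-12)
            assert vec["pI"] == pytest.approx(ft.isoelectric_point(seq), abs=1e-12)
            assert vec["Instability index"] == pytest.approx(
                ft.instability_index(seq), abs=1e-12
            )
            assert vec["Hydrophobicity"] == pytest.approx(
                ft.hydrophobicity(seq), abs=1e-12
            )

    def test_vectorized_path_agrees_with_scalar(self, peptides_50):
        frame = ft.featurize_many(peptides_50)
        assert frame.shape == (50, 23)
        for seq in peptides_50[:10]:
            scalar = ft.featurize(seq)
            np.testing.assert_allclose(
                frame.loc[seq].to_numpy(), scalar.to_numpy(), atol=1e-9
            )

    def test_matches_brute_force_oracles(self, peptides_50):
        frame = ft.featurize_many(peptides_50)
        for seq in peptides_50:
            expected = oracle_feature_vector(seq)
            for name in ft.FEATURE_NAMES:
                assert frame.loc[seq, name] == pytest.approx(
                    expected[name], abs=1e-9
                ), name
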