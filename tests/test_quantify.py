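"""Isotope-dilution quantification: pairing, averaging rule, ULQ, LLOQ, matrix."""

import numpy as np
import pandas as pd
import pytest

from qtap import (ConfigurationError, DataIntegrityError, ExpressionMatrix,
                  build_expression_matrix, determine_lloq, generate_mrm_dataset,
                  pair_transitions, quantify_dataset, quantify_peptide)
from qtap.quantify import STATUS_QUANTIFIED, STATUS_ULQ

from conftest import design_of


def _records(rows):
    return pd.DataFrame(rows, columns=["sample_id", "protein", "peptide",
                                       "transition_id", "label", "peak_area",
                                       "detected"])


def _pairs_one_peptide(ratios, heavy=1000.0, detected=None):
    detected = detected or [True] * len(ratios)
    rows = []
    for k, (r, d) in enumerate(zip(ratios, detected)):
        rows.append(("s1", "P", "PEP", f"T{k+1}", "light", r * heavy, d))
        rows.append(("s1", "P", "PEP", f"T{k+1}", "heavy", heavy, True))
    pairs, unpaired = pair_transitions(_records(rows))
    assert len(unpaired) == 0
    return pairs


class TestPairing:
    def test_four_light_four_heavy_gives_four_pairs(self):
        pairs = _pairs_one_peptide([0.5, 0.5, 0.5, 0.5])
        assert len(pairs) == 4

    def test_combinatorial_pair_count(self):
        rows = [(s, "P", pep, f"T{k}", lab, 100.0, True)
                for s in ("s1", "s2") for pep in ("A", "B")
                for k in range(3) for lab in ("light", "heavy")]
        pairs, unpaired = pair_transitions(_records(rows))
        assert len(pairs) == 12 and len(unpaired) == 0

    def test_light_without_heavy_reported_not_dropped(self):
        rows = [("s1", "P", "PEP", "T1", "light", 100.0, True),
                ("s1", "P", "PEP", "T2", "light", 100.0, True),
                ("s1", "P", "PEP", "T2", "heavy", 100.0, True)]
        pairs, unpaired = pair_transitions(_records(rows))
        assert len(pairs) == 1
        assert unpaired.to_dict("records") == [
            {"sample_id": "s1", "protein": "P", "peptide": "PEP",
             "transition_id": "T1", "missing_label": "heavy"}]

    def test_duplicate_rows_raise_data_integrity_error(self):
        rows = [("s1", "P", "PEP", "T1", "light", 100.0, True)] * 2
        with pytest.raises(DataIntegrityError, match="duplicate"):
            pair_transitions(_records(rows))


class TestQuantifyPeptide:
    def test_mean_of_three_equal_ratios(self):
        q = quantify_peptide(_pairs_one_peptide([0.5, 0.5, 0.5]),
                             spike_fmol=10, protein_load_ug=50)
        assert q.status == STATUS_QUANTIFIED
        assert q.expression == pytest.approx(0.1, rel=1e-12)

    def test_hand_computed_mean_of_four_ratios(self):
        q = quantify_peptide(_pairs_one_peptide([0.8, 1.0, 1.2, 1.0]),
                             spike_fmol=5, protein_load_ug=50)
        assert q.n_detected == 4
        assert q.transition_values == pytest.approx((0.08, 0.10, 0.12, 0.10))
        assert q.expression == pytest.approx(0.1, rel=1e-12)

    def test_two_detected_transitions_is_ulq_without_expression(self):
        pairs = _pairs_one_peptide([0.5, 0.5, 0.5],
                                   detected=[True, True, False])
        q = quantify_peptide(pairs, spike_fmol=10, protein_load_ug=50, lloq=0.15)
        assert q.status == STATUS_ULQ
        assert q.expression is None and q.lloq == 0.15 and q.n_detected == 2

    def test_detected_pair_with_zero_heavy_area_is_integrity_error(self):
        pairs = _pairs_one_peptide([0.5, 0.5, 0.5])
        pairs.loc[0, "heavy_area"] = 0.0
        with pytest.raises(DataIntegrityError, match="internal standard"):
            quantify_peptide(pairs, spike_fmol=10, protein_load_ug=50)

    @pytest.mark.parametrize("spike,load", [(0, 50), (10, 0), (-1, 50)])
    def test_nonpositive_spike_or_load_rejected(self, spike, load):
        with pytest.raises(ConfigurationError):
            quantify_peptide(_pairs_one_peptide([0.5] * 3), spike, load)


class TestLLOQ:
    def test_lowest_level_with_three_transitions(self):
        assert determine_lloq({0.01: 1, 0.03: 3, 0.1: 4}) == 0.03

    def test_all_levels_qualify_returns_lowest(self):
        assert determine_lloq({0.01: 4, 0.03: 4, 0.1: 4}) == 0.01

    def test_no_level_qualifies_is_not_quantifiable(self):
        assert determine_lloq({0.01: 1, 0.03: 2}) is None

    def test_non_monotone_series_warns_but_returns_lowest_qualifying(self):
        with pytest.warns(UserWarning, match="non-monotone"):
            assert determine_lloq({0.01: 3, 0.03: 2, 0.1: 4}) == 0.01

    def test_single_level_series_rejected(self):
        with pytest.raises(ConfigurationError):
            determine_lloq({0.1: 4})


class TestExpressionMatrix:
    def test_noiseless_end_to_end_recovers_ground_truth(self, noiseless_dataset):
        cfg, records, truth = noiseless_dataset
        quants, _ = quantify_dataset(records, cfg.spike_fmol, cfg.protein_load_ug)
        expected = truth.set_index(["protein", "sample_id"])
        for q in quants:
            true = expected.loc[(q.protein, q.sample_id),
                                "true_abundance_fmol_per_ug"]
            if q.quantified:
                assert q.expression == pytest.approx(true, rel=1e-12)
            else:
                assert true < cfg.noiseless_lloq

    def test_no_quantified_value_below_lloq_in_noiseless_mode(self, noiseless_config):
        cfg = noiseless_config
        records, _ = generate_mrm_dataset(cfg)
        quants, _ = quantify_dataset(records, cfg.spike_fmol, cfg.protein_load_ug)
        for q in quants:
            if q.quantified:
                assert q.expression >= cfg.noiseless_lloq

    def test_matrix_shape_flags_and_group_values(self, noiseless_dataset):
        cfg, records, _ = noiseless_dataset
        quants, _ = quantify_dataset(records, cfg.spike_fmol, cfg.protein_load_ug,
                                     {"OCT1": 0.15})
        matrix = build_expression_matrix(quants, design_of(records))
        assert matrix.values.shape == (3, 8)
        assert (matrix.flags.loc["OCT1"] == "ULQ").all()
        assert (matrix.flags.loc["ASCT1"] == "value").all()
        assert len(matrix.group_values("OCT1", "WT")) == 0
        np.testing.assert_allclose(matrix.group_values("ASCT1", "WT"), 0.71)

    def test_two_peptides_for_one_protein_is_configuration_error(self):
        rows = ([("s1", "P", "PEP1", f"T{k}", lab, 100.0, True)
                 for k in range(3) for lab in ("light", "heavy")]
                + [("s2", "P", "PEP2", f"T{k}", lab, 100.0, True)
                   for k in range(3) for lab in ("light", "heavy")])
        quants, _ = quantify_dataset(_records(rows), 10, 50)
        with pytest.raises(ConfigurationError, match="1:1"):
            build_expression_matrix(quants, {"s1": "WT", "s2": "WT"})

    def test_csv_round_trip_preserves_flags_and_values(self, noiseless_dataset, tmp_path):
        cfg, records, _ = noiseless_dataset
        quants, _ = quantify_dataset(records, cfg.spike_fmol, cfg.protein_load_ug,
                                     {"OCT1": 0.15})
        matrix = build_expression_matrix(quants, design_of(records))
        path = tmp_path / "matrix.csv"
        matrix.to_csv(path)
        back = ExpressionMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.flags, matrix.flags)
        np.testing.assert_allclose(back.values.to_numpy(dtype=float),
                                   matrix.values.to_numpy(dtype=float), rtol=1e-12)
        assert back.lloq["OCT1"] == 0.15
        assert list(back.design) == list(matrix.design)


class TestScaleInvariants:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_light_scaling_multiplies_expression(self, c):
        base = quantify_peptide(_pairs_one_peptide([0.8, 1.0, 1.2]), 10, 50)
        pairs = _pairs_one_peptide([0.8, 1.0, 1.2])
        pairs["light_area"] *= c
        scaled = quantify_peptide(pairs, 10, 50)
        assert scaled.expression == pytest.approx(c * base.expression, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_heavy_scaling_divides_expression(self, c):
        base = quantify_peptide(_pairs_one_peptide([0.8, 1.0, 1.2]), 10, 50)
        pairs = _pairs_one_peptide([0.8, 1.0, 1.2])
        pairs["heavy_area"] *= c
        scaled = quantify_peptide(pairs, 10, 50)
        assert scaled.expression == pytest.approx(base.expression / c, rel=1e-12)

    def test_doubling_protein_load_halves_expression(self):
        q1 = quantify_peptide(_pairs_one_peptide([0.8, 1.0, 1.2]), 10, 50)
        q2 = quantify_peptide(_pairs_one_peptide([0.8, 1.0, 1.2]), 10, 100)
        assert q2.expression == pytest.approx(q1.expression / 2, rel=1e-12)
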