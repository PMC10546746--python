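"""Logo layer geometry, mutation, faceting and composition."""

import numpy as np
import pytest

from seqlayers import (DNA, HeightMatrix, SequenceSet, build_align, build_bar,
                       build_logo, compose, mutate_layer, to_bits)
from seqlayers.logo import LETTER_WIDTH


def recovered_heights(layer):
    """Letter heights read back from polygon y extents, per (panel, pos, letter)."""
    out = {}
    for (grp, pos, letter), rows in layer.data.groupby(
            ["seq_group", "position", "letter"]):
        out[(grp, pos, letter)] = rows["y"].max() - rows["y"].min()
    return out


class TestBuildLogo:
    def test_conserved_column_bits_spans_two(self):
        layer = build_logo(["G", "G", "G"], method="bits")
        ys = layer.data["y"]
        assert ys.min() == pytest.approx(0.0, abs=1e-9)
        assert ys.max() == pytest.approx(2.0, abs=1e-9)
        assert set(layer.data["letter"]) == {"G"}

    def test_probability_tops_at_most_one(self):
        layer = build_logo(["ACGT", "ACGA", "TCGA"], method="probability")
        assert layer.data["y"].max() <= 1 + 1e-9
        assert layer.ylab == "probability"

    def test_column_sums_equal_height_matrix_sums(self):
        seqs = ["ACGT", "ACGA", "TCGA", "ACTA"]
        layer = build_logo(seqs, method="bits")
        hm = layer.heights["1"]
        rec = recovered_heights(layer)
        for j in range(hm.n_positions):
            total = sum(v for (g, p, l), v in rec.items() if p == j + 1)
            assert total == pytest.approx(hm.heights[:, j].sum(), abs=1e-9)

    def test_letters_stay_inside_position_slot(self):
        layer = build_logo(["ACGT", "AGGT"], method="probability")
        for pos, rows in layer.data.groupby("position"):
            assert rows["x"].min() >= pos - 0.5 - 1e-9
            assert rows["x"].max() <= pos + 0.5 + 1e-9
            assert rows["x"].max() - rows["x"].min() == pytest.approx(
                LETTER_WIDTH, abs=1e-9)

    def test_custom_heights_straddle_axis(self):
        m = np.array([[1.0], [-0.5], [0.0], [0.0]])
        layer = build_logo(m, method="custom", namespace=DNA)
        groups = layer.data.groupby("letter")["y"]
        assert groups.min()["A"] == pytest.approx(0.0, abs=1e-9)
        assert groups.max()["A"] == pytest.approx(1.0, abs=1e-9)
        assert groups.min()["C"] == pytest.approx(-0.5, abs=1e-9)
        assert groups.max()["C"] == pytest.approx(0.0, abs=1e-9)
        assert layer.ylab == ""

    def test_custom_round_trip_recovers_matrix(self):
        rng = np.random.default_rng(42)
        m = np.round(rng.uniform(-2, 2, size=(4, 5)), 3)
        m[np.abs(m) < 0.05] = 0.0
        layer = build_logo(m, method="custom", namespace=DNA)
        rec = recovered_heights(layer)
        for i, letter in enumerate(DNA):
            for j in range(5):
                expected = abs(m[i, j])
                got = rec.get(("1", j + 1, letter), 0.0)
                assert got == pytest.approx(expected, abs=1e-9)

    def test_custom_with_sequences_is_a_type_error(self):
        with pytest.raises(TypeError, match="custom"):
            build_logo(["ACGT"], method="custom")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_logo([])

    def test_height_matrix_input_used_verbatim(self):
        hm = HeightMatrix(DNA, np.array([[0.2], [0.8], [0.0], [0.0]]),
                          "probability")
        layer = build_logo(hm, method="probability")
        rec = recovered_heights(layer)
        assert rec[("1", 1, "C")] == pytest.approx(0.8, abs=1e-9)

    def test_facet_panels_follow_mapping_key_order(self):
        layer = build_logo({"b": ["ACG"], "a": ["TTT"], "c": ["GGG"]},
                           method="probability")
        assert layer.panel_labels == ["b", "a", "c"]
        assert list(dict.fromkeys(layer.data["seq_group"])) == ["b", "a", "c"]

    def test_flat_input_single_panel_labeled_one(self):
        layer = build_logo(["ACG"], method="probability")
        assert layer.panel_labels == ["1"]
        assert set(layer.data["seq_group"]) == {"1"}


class TestMutateLayer:
    def test_per_position_recolor(self):
        layer = build_logo(["ACGT", "ACGT"], method="probability")
        edited = mutate_layer(layer, [
            {"letter": "A", "position": 1, "col": "#FF0000"},
            {"letter": "T", "position": 4, "col": "#808080"},
        ])
        a1 = edited.data.query("letter == 'A' and position == 1")["col"]
        t4 = edited.data.query("letter == 'T' and position == 4")["col"]
        assert set(a1) == {"#FF0000"}
        assert set(t4) == {"#808080"}
        # original untouched
        assert "#FF0000" not in set(layer.data["col"])

    def test_empty_edit_set_is_identity(self):
        layer = build_logo(["ACGT"], method="bits")
        assert mutate_layer(layer, []).data.equals(layer.data)

    def test_edits_preserve_geometry_columns(self):
        layer = build_logo(["ACGT", "AGGT"], method="bits")
        edited = mutate_layer(layer, [{"letter": "A", "col": "#123456"}])
        for col in ("x", "y", "piece", "order", "position"):
            assert edited.data[col].equals(layer.data[col])

    def test_missing_record_is_an_edit_error(self):
        layer = build_logo(["ACGT"], method="bits")
        with pytest.raises(KeyError):
            mutate_layer(layer, [{"letter": "A", "position": 99,
                                  "col": "#FF0000"}])

    def test_geometry_edits_refused(self):
        layer = build_logo(["ACGT"], method="bits")
        with pytest.raises(ValueError):
            mutate_layer(layer, [{"letter": "A", "y": 5.0}])


class TestCompose:
    def test_single_layer_zero_offset_identity(self):
        layer = build_logo(["ACGT"], method="bits")
        combined = compose([layer], [0.0])
        assert len(combined) == len(layer.data)
        assert np.allclose(combined["y"], layer.data["y"])

    def test_offset_separates_logo_from_alignment(self):
        seqs = ["ACGT", "ACGA", "TCGA"]
        aln = build_align(seqs)
        logo = build_logo(seqs, method="bits")
        combined = compose([aln, logo], [0.0, len(seqs)])
        aln_rows = combined[combined["layer"] == 0]
        logo_rows = combined[combined["layer"] == 1]
        aln_top = (aln_rows["y"] + aln_rows.get("height", 0) / 2).max()
        assert logo_rows["y"].min() >= aln_top - 1e-9

    def test_order_free_union(self):
        a = build_logo(["ACG"], method="bits")
        b = build_bar(["ACG", "ACC"])
        ab = compose([a, b], [0.0, 3.0])
        ba = compose([b, a], [3.0, 0.0])
        assert len(ab) == len(ba)
        assert set(ab.columns) == set(ba.columns)

    def test_inputs_not_mutated(self):
        layer = build_logo(["ACGT"], method="bits")
        before = layer.data.copy()
        compose([layer], [5.0])
        assert layer.data.equals(before)
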