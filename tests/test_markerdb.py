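"""Marker database parsing, specificity weights, coverage and derivation."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spottype import (
    GeneSpotMatrix,
    compute_specificity_weights,
    derive_markers_from_reference,
    load_marker_db,
    marker_coverage_report,
    reference_profiles,
    SimulationConfig,
)
from spottype.errors import FormatError, TissueLookupError, ValidationError

from conftest import make_db


class TestLoadMarkerDb:
    def test_parses_positive_and_empty_negative_lists(self, brain_db_path):
        db = load_marker_db(brain_db_path)
        astro = next(e for e in db.entries if e.cell_type == "Astrocyte")
        assert astro.positive_genes == {"GFAP", "AQP4"}
        assert astro.negative_genes == frozenset()

    def test_tissue_filter_restricts_entries(self, brain_db_path):
        db = load_marker_db(brain_db_path, tissue_filter="Brain")
        assert db.tissues() == ["Brain"]
        assert len(db.entries) == 3

    def test_symbols_case_folded_and_deduplicated(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "tissueType\tcellName\tgeneSymbolmore1\tgeneSymbolmore2\n"
            "Brain\tAstrocyte\tgfap , Gfap\t\n"
        )
        db = load_marker_db(path)
        assert db.entries[0].positive_genes == {"GFAP"}

    def test_missing_column_is_named_in_error(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text("tissueType\tcellName\tgeneSymbolmore1\nA\tB\tC\n")
        with pytest.raises(FormatError, match="geneSymbolmore2"):
            load_marker_db(path)

    def test_duplicate_tissue_cell_pair_rejected(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "tissueType\tcellName\tgeneSymbolmore1\tgeneSymbolmore2\n"
            "Brain\tAstrocyte\tGFAP\t\nBrain\tAstrocyte\tAQP4\t\n"
        )
        with pytest.raises(ValidationError, match="Astrocyte"):
            load_marker_db(path)

    def test_gene_in_both_lists_rejected_with_context(self, tmp_path):
        path = tmp_path / "db.tsv"
        path.write_text(
            "tissueType\tcellName\tgeneSymbolmore1\tgeneSymbolmore2\n"
            "Brain\tAstrocyte\tGFAP,AQP4\tGFAP\n"
        )
        with pytest.raises(ValidationError) as exc:
            load_marker_db(path)
        msg = str(exc.value)
        assert "GFAP" in msg and "Astrocyte" in msg

    def test_unknown_tissue_filter_errors(self, brain_db_path):
        with pytest.raises(TissueLookupError):
            load_marker_db(brain_db_path, tissue_filter="Liver")


class TestSpecificityWeights:
    @pytest.mark.parametrize(
        "n_marked, expected",
        [(1, 1.0), (5, 0.0), (3, 0.5), (2, 0.75)],
    )
    def test_linear_formula_over_five_cell_types(self, n_marked, expected):
        # gene X marks `n_marked` of 5 cell types; each type also has a
        # private anchor gene
        entries = [
            (f"CT{k}", {f"P{k}"} | ({"X"} if k < n_marked else set()), set())
            for k in range(5)
        ]
        w = compute_specificity_weights(make_db(entries), "T")
        assert w.weights["X"] == pytest.approx(expected)
        assert all(w.weights[f"P{k}"] == 1.0 for k in range(5))

    def test_single_cell_type_tissue_gives_weight_one(self):
        w = compute_specificity_weights(make_db([("A", {"G1", "G2"}, set())]), "T")
        assert set(w.weights.values()) == {1.0}

    def test_negative_list_membership_counts_once(self):
        # X positive in CT0, negative in CT1 -> n_g = 2 of N = 3
        db = make_db([
            ("CT0", {"X", "A"}, set()),
            ("CT1", {"B"}, {"X"}),
            ("CT2", {"C"}, set()),
        ])
        w = compute_specificity_weights(db, "T")
        assert w.weights["X"] == pytest.approx(0.5)

    def test_unknown_tissue_errors(self):
        with pytest.raises(TissueLookupError):
            compute_specificity_weights(make_db([("A", {"G"}, set())]), "Liver")

    @settings(max_examples=30, derandomize=True)
    @given(n=st.integers(min_value=2, max_value=12))
    def test_weight_strictly_decreasing_in_marking_count(self, n):
        weights = []
        for n_marked in range(1, n + 1):
            entries = [
                (f"CT{k}", {f"P{k}"} | ({"X"} if k < n_marked else set()), set())
                for k in range(n)
            ]
            weights.append(
                compute_specificity_weights(make_db(entries), "T").weights["X"]
            )
        assert all(a > b for a, b in zip(weights, weights[1:]))
        assert weights[0] == 1.0 and weights[-1] == 0.0

    def test_relabeling_cell_types_preserves_weights(self):
        entries = [("A", {"X", "PA"}, set()), ("B", {"X", "PB"}, {"Q"}),
                   ("C", {"PC"}, set())]
        renamed = [(f"Z-{ct}", pos, neg) for ct, pos, neg in entries]
        w1 = compute_specificity_weights(make_db(entries), "T")
        w2 = compute_specificity_weights(make_db(renamed), "T")
        assert w1.weights == w2.weights


class TestCoverageReport:
    def test_full_universe_gives_fraction_one(self, brain_db_path):
        db = load_marker_db(brain_db_path, tissue_filter="Brain")
        report = marker_coverage_report(db, "Brain", db.all_genes("Brain"))
        assert (report.per_cell_type["fraction_detected"] == 1.0).all()

    def test_disjoint_universe_detects_nothing(self, brain_db_path):
        db = load_marker_db(brain_db_path, tissue_filter="Brain")
        report = marker_coverage_report(db, "Brain", {"ZZZ1", "ZZZ2"})
        assert (report.per_cell_type["n_positive_detected"] == 0).all()
        assert report.db_genes_detected == 0

    def test_partial_overlap_counts(self):
        db = make_db([("CT", {"A", "B", "C", "D"}, set())])
        report = marker_coverage_report(db, "T", {"A", "B", "X"})
        row = report.per_cell_type.iloc[0]
        assert row["n_positive_detected"] == 2
        assert row["fraction_detected"] == pytest.approx(0.5)

    def test_rows_lexicographic_and_universe_canonicalized(self):
        db = make_db([("Zeta", {"A"}, set()), ("Alpha", {"B"}, set())])
        report = marker_coverage_report(db, "T", {" a ", "a", "b", "b"})
        assert report.per_cell_type["cell_type"].tolist() == ["Alpha", "Zeta"]
        assert report.genes_in_universe == 2
        assert report.db_genes_detected == 2

    def test_empty_universe_rejected(self):
        db = make_db([("CT", {"A"}, set())])
        with pytest.raises(ValidationError):
            marker_coverage_report(db, "T", set())


class TestDeriveMarkers:
    def _expr(self, values, genes, profiles):
        return GeneSpotMatrix(
            values=np.asarray(values, float), gene_ids=genes,
            spot_ids=profiles, layer="counts",
        )

    def test_dominant_gene_becomes_sole_marker(self):
        expr = self._expr([[5, 5, 0, 0], [1, 1, 1, 1]], ["G1", "G2"],
                          ["a1", "a2", "b1", "b2"])
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        db = derive_markers_from_reference(expr, labels, top_n=1, tissue="T")
        a = next(e for e in db.entries if e.cell_type == "A")
        assert a.positive_genes == {"G1"}

    def test_identical_expression_yields_empty_sets_and_warns(self, caplog):
        expr = self._expr([[2, 2, 2, 2]], ["G1"], ["a1", "a2", "b1", "b2"])
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        with caplog.at_level(logging.WARNING):
            db = derive_markers_from_reference(expr, labels, top_n=1, tissue="T")
        assert all(e.positive_genes == frozenset() for e in db.entries)
        assert any("positive specificity score" in r.message for r in caplog.records)

    def test_hand_computed_three_label_toy(self):
        # constant within-label columns, so log1p means are exact:
        #   G1: A=5 others 0; G2: A=3, B=1; G3: B=4; G4: C=4, B=1;
        #   G5: flat 2; G6: A=2, C=2
        genes = ["G1", "G2", "G3", "G4", "G5", "G6"]
        cols = {"A": [5, 3, 0, 0, 2, 2], "B": [0, 1, 4, 1, 2, 0],
                "C": [0, 0, 0, 4, 2, 2]}
        profiles, values = [], []
        for lab in "ABC":
            for rep in (1, 2, 3):
                profiles.append(f"{lab}{rep}")
                values.append(cols[lab])
        expr = self._expr(np.array(values).T, genes, profiles)
        labels = {p: p[0] for p in profiles}
        db = derive_markers_from_reference(expr, labels, top_n=2, tissue="T")
        by_type = {e.cell_type: e.positive_genes for e in db.entries}
        assert by_type == {"A": {"G1", "G2"}, "B": {"G3"}, "C": {"G4"}}

    def test_fewer_than_two_labels_rejected(self):
        expr = self._expr([[1, 2]], ["G1"], ["p1", "p2"])
        with pytest.raises(ValidationError):
            derive_markers_from_reference(expr, {"p1": "A", "p2": "A"}, 1, "T")

    def test_unlabeled_profile_rejected(self):
        expr = self._expr([[1, 2]], ["G1"], ["p1", "p2"])
        with pytest.raises(ValidationError, match="p2"):
            derive_markers_from_reference(expr, {"p1": "A"}, 1, "T")

    def test_recovers_planted_blocks_from_noiseless_profiles(self):
        config = SimulationConfig()
        expr, labels = reference_profiles(config)
        db = derive_markers_from_reference(
            expr, labels, top_n=config.markers_per_type, tissue="T"
        )
        for e in db.entries:
            assert e.positive_genes == set(config.marker_blocks[e.cell_type])
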