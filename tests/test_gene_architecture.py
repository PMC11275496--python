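"""Circular gene-order analytics: overlaps, spacers, adjacencies, classes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitochar import analyze_architecture, class_length_summary, strand_inventory
from mitochar.errors import FeatureValidationError
from mitochar.io_genbank import GeneFeature
from mitochar.synthetic_data import rotate_origin


def occupancy_oracle(genome_length, features):
    """Independent per-position oracle: overlap bp = coverage excess
    (sum of coverage-1 over covered positions); spacer bp = uncovered."""
    cov = np.zeros(genome_length, dtype=int)
    for f in features:
        cov[f.start - 1:f.end] += 1
    return int(np.maximum(cov - 1, 0).sum()), int((cov == 0).sum())


def mk(name, start, end, strand="H", fclass="PCG"):
    return GeneFeature(name=name, feature_class=fclass, strand=strand,
                       start=start, end=end)


@st.composite
def feature_sets(draw):
    length = draw(st.integers(200, 2000))
    n = draw(st.integers(1, 50))
    feats = []
    for i in range(n):
        s = draw(st.integers(1, length - 1))
        e = draw(st.integers(s, min(length, s + draw(st.integers(0, 300)))))
        feats.append(mk(f"g{i:02d}", s, e))
    return length, feats


@pytest.fixture(scope="module")
def report(ref_features, ref_length):
    return analyze_architecture(ref_length, ref_features, circular=True)


class TestPublishedAnnotation:
    """Architecture numbers recomputed from the transcribed annotation."""

    def test_nine_overlaps_totaling_32_bp(self, report):
        assert report.overlap_count == 9
        assert report.overlap_bp == 32

    def test_22_spacers_totaling_402_bp_within_closing_convention(self, report):
        """22 intergenic intervals; the through-origin closing interval is
        297 bp by arithmetic on the declared length (one more than the
        printed 296), so the total is 402 +/- 1 bp."""
        assert report.spacer_count == 22
        assert abs(report.spacer_bp - 402) <= 1
        assert report.closing_spacer == ("d-loop", "trnF", 297)
        non_closing = [bp for pair in report.spacers
                       for bp in [pair[2]] if pair != report.closing_spacer]
        assert sum(non_closing) == 106
        assert 1 <= min(non_closing) and max(non_closing) == 17

    def test_seven_exact_adjacencies(self, report):
        assert report.adjacency_count == 7

    def test_spacer_fraction_against_annotated_span(self, report):
        # 402/16518 = 2.43% when measured against the last annotated base
        # (closing interval at its printed 296-bp value)
        frac = (report.spacer_bp - 1) / report.annotated_span
        assert round(100 * frac, 2) == 2.43
        assert report.spacer_fractions()["of_annotated_span"] == \
            pytest.approx(report.spacer_bp / 16518)

    def test_nine_l_strand_genes(self, ref_features):
        inv = strand_inventory(ref_features)
        assert inv["L"]["count"] == 9
        assert set(inv["L"]["genes"]) == {
            "trnQ", "trnA", "trnN", "trnC", "trnY", "trnS2", "trnP", "trnE",
            "nad6",
        }
        assert inv["L"]["by_class"] == {"tRNA": 8, "PCG": 1}

    def test_class_length_totals(self, ref_features, ref_length):
        cls = class_length_summary(ref_length, ref_features)
        assert cls["tRNA"]["total_bp"] == 1546
        assert cls["tRNA"]["min"] == ("trnS1", 66)
        assert cls["tRNA"]["max"][1] == 75  # trnL2 and trnS2 both reach 75
        assert cls["rRNA"]["min"] == ("rrnS", 980)
        assert cls["rRNA"]["max"] == ("rrnL", 1579)
        assert cls["control_region"]["total_bp"] == 950
        by_name = {f.name: f for f in ref_features}
        assert by_name["nad5"].length == 1818
        assert by_name["atp8"].length == 168


class TestPairClassification:
    def test_adjacency_on_a_tiny_circle(self):
        feats = [mk("a", 1, 10), mk("b", 11, 20)]
        rep = analyze_architecture(20, feats, circular=True)
        assert rep.adjacency_count == 2  # b after a, and a after b via origin
        assert rep.overlap_count == 0 and rep.spacer_count == 0

    def test_every_pair_in_exactly_one_bucket(self, ref_features, ref_length):
        rep = analyze_architecture(ref_length, ref_features)
        n_pairs = len(ref_features)  # circular: one pair per feature
        assert rep.overlap_count + rep.spacer_count + rep.adjacency_count == n_pairs

    def test_nested_feature_flagged_and_conserved(self):
        feats = [mk("outer", 1, 50), mk("inner", 10, 20), mk("c", 60, 80)]
        rep = analyze_architecture(100, feats, circular=True)
        assert ("outer", "inner") in rep.nested
        total = sum(f.length for f in feats)
        assert total - rep.overlap_bp + rep.spacer_bp == 100

    def test_feature_beyond_genome_rejected(self):
        with pytest.raises(FeatureValidationError):
            analyze_architecture(50, [mk("a", 40, 60)])

    def test_single_gene_spanning_genome_has_fraction_one(self):
        feats = [mk("a", 1, 100)]
        cls = class_length_summary(100, feats)
        assert cls["PCG"]["fraction_of_genome"] == 1.0

    def test_all_h_input_gives_empty_l_list(self):
        inv = strand_inventory([mk("a", 1, 5), mk("b", 10, 20)])
        assert inv["L"]["genes"] == [] and inv["H"]["count"] == 2


class TestOracleAndInvariants:
    @given(feature_sets())
    def test_totals_equal_occupancy_oracle(self, case):
        length, feats = case
        rep = analyze_architecture(length, feats, circular=True)
        ov, sp = occupancy_oracle(length, feats)
        assert rep.overlap_bp == ov
        assert rep.spacer_bp == sp

    @given(feature_sets())
    def test_circular_length_conservation(self, case):
        length, feats = case
        rep = analyze_architecture(length, feats, circular=True)
        total = sum(f.length for f in feats)
        assert total - rep.overlap_bp + rep.spacer_bp == length

    @pytest.mark.parametrize("offset", [1, 500, 5034, 16514])
    def test_rotation_invariance(self, synthetic_bundle, offset):
        genome, feats, _ = synthetic_bundle
        rep0 = analyze_architecture(genome.length, feats)
        g2, f2 = rotate_origin(genome, feats, offset)
        rep2 = analyze_architecture(g2.length, f2)
        assert (rep2.overlap_bp, rep2.spacer_bp) == (rep0.overlap_bp,
                                                     rep0.spacer_bp)

    def test_strand_ignored_for_pairing(self):
        """H and L genes interleave in one linear order for pairing."""
        feats = [mk("a", 1, 10, "H"), mk("b", 8, 20, "L"), mk("c", 25, 30, "H")]
        rep = analyze_architecture(40, feats)
        assert ("a", "b", 3) in rep.overlaps
        assert ("b", "c", 4) in rep.spacers
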