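"""Codon extraction, incomplete stop typing and RSCU."""

from collections import Counter

import pytest
from hypothesis import given, strategies as st

from mitochar import (
    CircularGenome, count_codons, extract_codons, rscu, rscu_from_counts,
)
from mitochar.codon_usage import (
    MITO_STOPS, CodonUsageTable, codon_families, to_rna,
)
from mitochar.errors import FeatureValidationError
from mitochar.io_genbank import GeneFeature, revcomp


def pcg(seq_len, start=1, strand="H", name="nad1"):
    return GeneFeature(name=name, feature_class="PCG", strand=strand,
                       start=start, end=start + seq_len - 1)


class TestExtractCodons:
    def test_minimal_complete_gene(self):
        genome = CircularGenome(id="x", length=9, seq="ATGAAATAA")
        rec = extract_codons(genome, pcg(9))
        assert rec.start_codon == "ATG" and rec.stop_codon == "TAA"
        assert rec.codons == ["ATG", "AAA", "TAA"]
        assert rec.length == 9

    def test_incomplete_stop_ta(self):
        genome = CircularGenome(id="x", length=8, seq="ATGAAATA")
        rec = extract_codons(genome, pcg(8))
        assert rec.stop_codon == "TA-" and rec.stop_remainder == 2
        assert rec.codons == ["ATG", "AAA"]

    def test_incomplete_stop_t(self):
        genome = CircularGenome(id="x", length=7, seq="ATGAAAT")
        rec = extract_codons(genome, pcg(7))
        assert rec.stop_codon == "T--" and rec.stop_remainder == 1

    def test_inconsistent_remainder_flagged(self):
        genome = CircularGenome(id="x", length=7, seq="ATGAAAG")
        rec = extract_codons(genome, pcg(7))
        assert rec.stop_codon is None
        assert any("annotation-inconsistent" in w for w in rec.warnings)

    def test_l_strand_gene_read_on_reverse_complement(self):
        sense = "ATGAAATAA"
        genome = CircularGenome(id="x", length=9, seq=revcomp(sense))
        rec = extract_codons(genome, pcg(9, strand="L"))
        assert rec.codons == ["ATG", "AAA", "TAA"]

    def test_internal_stop_warned_not_fatal(self):
        genome = CircularGenome(id="x", length=12, seq="ATGAGAAAATAA")
        rec = extract_codons(genome, pcg(12))
        assert any("internal stop" in w for w in rec.warnings)
        assert rec.stop_codon == "TAA"

    def test_planted_stop_types_recovered(self, synthetic_bundles):
        """Incomplete stops planted by the generator are recovered 100%;
        complete stops match the truth re-derived from the emitted genome."""
        for genome, feats, truth in synthetic_bundles:
            for f in feats:
                if f.feature_class != "PCG":
                    continue
                rec = extract_codons(genome, f)
                assert rec.stop_codon == truth.stop_codons[f.name]
            incomplete = {g for g, s in truth.stop_codons.items()
                          if s in ("TA-", "T--")}
            assert incomplete == {"nad1", "cox3", "nad4"}

    def test_vertebrate_mito_stop_set(self):
        assert MITO_STOPS == {"TAA", "TAG", "AGA", "AGG"}


class TestCountCodons:
    def test_two_copies_of_a_gene(self):
        genome = CircularGenome(id="x", length=12, seq="ATGTAAATGTAA")
        recs = [extract_codons(genome, pcg(6, start=1, name="nad1")),
                extract_codons(genome, pcg(6, start=7, name="nad2"))]
        table = count_codons(recs, include_stops=True)
        assert table.counts["AUG"] == 2 and table.counts["UAA"] == 2

    def test_exclude_stops_drops_terminal_triplet(self):
        genome = CircularGenome(id="x", length=9, seq="ATGAAATAA")
        table = count_codons([extract_codons(genome, pcg(9))],
                             include_stops=False)
        assert table.counts["UAA"] == 0 and table.counts["AUG"] == 1

    def test_counts_equal_generator_tally(self, synthetic_bundle):
        genome, feats, truth = synthetic_bundle
        recs = [extract_codons(genome, f) for f in feats
                if f.feature_class == "PCG"]
        table = count_codons(recs, include_stops=True)
        for codon, n in truth.codon_counts.items():
            assert table.counts[codon] == n
        assert sum(table.counts.values()) == sum(truth.codon_counts.values())

    def test_total_codons_equal_floor_lengths_over_three(self, synthetic_bundle):
        genome, feats, truth = synthetic_bundle
        recs = [extract_codons(genome, f) for f in feats
                if f.feature_class == "PCG"]
        table = count_codons(recs, include_stops=True)
        expected = sum(f.length // 3 for f in feats if f.feature_class == "PCG")
        assert sum(table.counts.values()) == expected


class TestRscu:
    def test_published_leucine_family(self, ref_codon_counts):
        """The six-codon Leu family count vector gives RSCU(CUA) = 2.35."""
        table = rscu_from_counts(ref_codon_counts)
        leu = {"UUA": 83, "UUG": 38, "CUU": 98, "CUC": 128, "CUA": 265,
               "CUG": 66}
        assert {c: table.counts[c] for c in leu} == leu
        assert round(table.rscu["CUA"], 2) == 2.35

    def test_published_alanine_family(self, ref_codon_counts):
        table = rscu_from_counts(ref_codon_counts)
        assert {c: table.counts[c] for c in ("GCU", "GCC", "GCA", "GCG")} == \
            {"GCU": 65, "GCC": 153, "GCA": 94, "GCG": 21}
        assert round(table.rscu["GCG"], 2) == 0.25

    def test_uniform_counts_give_rscu_one(self):
        fam = codon_families("standard")["L"]
        table = rscu_from_counts({c: 7 for c in fam})
        assert all(table.rscu[c] == pytest.approx(1.0) for c in fam)

    def test_family_mean_is_one_whenever_observed(self, ref_codon_counts):
        table = rscu_from_counts(ref_codon_counts)
        for aa, fam in table.families.items():
            vals = [table.rscu[c] for c in fam]
            if any(v is not None for v in vals):
                assert sum(vals) / len(vals) == pytest.approx(1.0, abs=1e-9)

    def test_zero_family_reported_blank(self):
        table = rscu_from_counts({"AUG": 5})  # nothing else observed
        fam = codon_families("standard")["L"]
        assert all(table.rscu[c] is None for c in fam)
        assert table.rscu["AUG"] == 1.0  # singleton family

    @given(st.integers(1, 1000))
    def test_scaling_invariance(self, k):
        counts = {"GCU": 3, "GCC": 9, "GCA": 1, "GCG": 2}
        t1 = rscu_from_counts(counts)
        t2 = rscu_from_counts({c: k * n for c, n in counts.items()})
        for c in counts:
            assert t1.rscu[c] == pytest.approx(t2.rscu[c])

    def test_mito_family_partition_differs_where_the_codes_differ(self):
        std = codon_families("standard")
        mito = codon_families("mito")
        assert len(std["R"]) == 6 and len(mito["R"]) == 4  # AGA/AGG -> stops
        assert set(std["*"]) == {"UAA", "UAG", "UGA"}
        assert set(mito["*"]) == {"UAA", "UAG", "AGA", "AGG"}
        assert set(mito["W"]) == {"UGA", "UGG"}
        assert set(mito["M"]) == {"AUA", "AUG"}

    def test_negative_counts_rejected(self):
        with pytest.raises(FeatureValidationError):
            CodonUsageTable(counts={"AUG": -1})
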