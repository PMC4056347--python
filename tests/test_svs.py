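"""SV-signal clustering, somatic subtraction, gene breakage, fusion
calling and reading-frame prediction."""

import numpy as np
import pandas as pd
import pytest

from gcprofiler.genes import GeneModel, genes_by_id
from gcprofiler.svs import (SVS, FusionCandidate, LibraryStats,
                            call_fusions, classify_pair, cluster_svs,
                            gene_breakage, predict_fusion_transcript,
                            somatic_svs, summarize_sv_counts,
                            total_from_class_means)

STATS = LibraryStats(median_insert=400.0, mad=40.0, k=3.0)
PAIR_COLS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
             "uniquely_mapped"]


def _pairs(rows):
    return pd.DataFrame(rows, columns=PAIR_COLS)


def _cluster_rows(pos1, pos2, n, chrom1="chr1", chrom2="chr1",
                  strands=("+", "-")):
    return [(chrom1, pos1, strands[0], chrom2, pos2, strands[1], True)
            for _ in range(n)]


class TestClassifyPair:
    def test_interchromosomal(self):
        assert classify_pair("chr1", 100, "+", "chr2", 100, "-",
                             STATS) == "inter_translocation"

    def test_concordant_span_is_none(self):
        assert classify_pair("chr1", 0, "+", "chr1", 400, "-", STATS) is None

    def test_long_span_deletion(self):
        # span = median + 10 * MAD, well past the k=3 gate
        assert classify_pair("chr1", 0, "+", "chr1", 800, "-",
                             STATS) == "deletion"

    def test_short_span_insertion(self):
        assert classify_pair("chr1", 0, "+", "chr1", 100, "-",
                             STATS) == "insertion"

    def test_same_strand_inversion(self):
        assert classify_pair("chr1", 0, "+", "chr1", 5000, "+",
                             STATS) == "inversion"

    def test_huge_span_intra_translocation(self):
        assert classify_pair("chr1", 0, "+", "chr1", 2_000_000, "-",
                             STATS) == "intra_translocation"

    def test_unnormalized_mate_order_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            classify_pair("chr2", 100, "+", "chr1", 100, "-", STATS)


class TestClusterSVS:
    def test_four_coincident_pairs_form_one_svs(self):
        out = cluster_svs(_pairs(_cluster_rows(1000, 500_000, 4)), STATS)
        assert len(out) == 1
        assert out[0].n_support == 4
        assert out[0].sv_type == "deletion"

    def test_three_pairs_insufficient(self):
        out = cluster_svs(_pairs(_cluster_rows(1000, 500_000, 3)), STATS)
        assert out == []

    def test_non_unique_pairs_excluded(self):
        rows = _cluster_rows(1000, 500_000, 4)
        rows[0] = rows[0][:-1] + (False,)
        assert cluster_svs(_pairs(rows), STATS) == []

    def test_join_distance_separates_clusters(self):
        rows = (_cluster_rows(1000, 500_000, 4)
                + _cluster_rows(1000 + 5000, 500_000 + 5000, 4))
        out = cluster_svs(_pairs(rows), STATS)
        assert len(out) == 2

    def test_order_invariant(self, rng):
        rows = (_cluster_rows(1000, 500_000, 5)
                + _cluster_rows(40_000, 700_000, 6)
                + [("chr1", 9000, "+", "chr2", 100, "-", True)])
        base = cluster_svs(_pairs(rows), STATS)
        for _ in range(10):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            assert cluster_svs(_pairs(perm), STATS) == base


def _svs(p1, p2, sv_type="deletion", n=5, chrom1="chr1", chrom2="chr1"):
    return SVS(chrom1, p1, p1 + 1, chrom2, p2, p2 + 1, sv_type, n)


class TestSomaticSubtraction:
    def test_blood_match_at_400bp_removed(self):
        tumor = [_svs(10_000, 500_000)]
        blood = [_svs(10_400, 500_400, sv_type="insertion")]
        assert somatic_svs(tumor, blood) == []

    def test_blood_at_401bp_retained(self):
        tumor = [_svs(10_000, 500_000)]
        blood = [_svs(10_401, 500_000)]
        assert somatic_svs(tumor, blood) == tumor

    def test_empty_blood_identity(self):
        tumor = [_svs(10_000, 500_000), _svs(1_000_000, 2_000_000)]
        assert somatic_svs(tumor, []) == tumor


GENE_A = GeneModel("geneA", "chr1", 10_000, 20_000, "+",
                   exon_starts=(10_000, 15_000), exon_ends=(11_000, 16_000),
                   cds_start=10_000, cds_end=16_000)
GENE_B = GeneModel("geneB", "chr2", 50_000, 60_000, "+",
                   exon_starts=(50_000, 55_000), exon_ends=(51_000, 56_000),
                   cds_start=50_000, cds_end=56_000)


class TestGeneBreakage:
    def test_intronic_breakpoint_impairs_gene(self):
        s = _svs(12_000, 500_000)  # bp1 in intron 1 of geneA
        assert gene_breakage([s], [GENE_A]) == {"geneA"}

    def test_intergenic_breakpoints_impair_nothing(self):
        s = _svs(30_000, 500_000)
        assert gene_breakage([s], [GENE_A]) == set()

    def test_exon_filter_drops_intron_only_svs(self):
        s = _svs(12_000, 500_000)  # both breakpoints outside exons
        assert gene_breakage([s], [GENE_A], exon_filter=True) == set()

    def test_exon_filter_keeps_exonic_svs(self):
        s = _svs(10_500, 500_000)  # bp1 inside exon 1
        assert gene_breakage([s], [GENE_A], exon_filter=True) == {"geneA"}


class TestFusionCalling:
    def _inter(self, n):
        return SVS("chr1", 12_000, 12_001, "chr2", 52_000, 52_001,
                   "inter_translocation", n)

    def test_eleven_pairs_accepted(self):
        out = call_fusions([self._inter(11)], [GENE_A, GENE_B])
        assert len(out) == 1
        assert (out[0].gene5, out[0].gene3) == ("geneA", "geneB")

    def test_ten_pairs_rejected(self):
        assert call_fusions([self._inter(10)], [GENE_A, GENE_B]) == []

    def test_intrachromosomal_rejected(self):
        gene_b1 = GeneModel("geneB1", "chr1", 50_000, 60_000, "+",
                            exon_starts=(50_000,), exon_ends=(60_000,),
                            cds_start=50_000, cds_end=60_000)
        s = SVS("chr1", 12_000, 12_001, "chr1", 52_000, 52_001,
                "deletion", 20)
        assert call_fusions([s], [GENE_A, gene_b1]) == []


class TestFusionFrame:
    # 5' partner: two 300-bp coding exons; breakpoint in the intron
    # keeps exon 1 -> retained CDS length 300 (codon-complete)
    G5 = GeneModel("g5", "chr1", 1000, 2300, "+",
                   exon_starts=(1000, 2000), exon_ends=(1300, 2300),
                   cds_start=1000, cds_end=2300)
    # 3' partner: two coding exons of 301 and 299 bp
    G3A = GeneModel("g3a", "chr2", 5000, 6600, "+",
                    exon_starts=(5000, 6301), exon_ends=(5301, 6600),
                    cds_start=5000, cds_end=6600)
    # 3' partner variant: first exon 300 bp (phase-0 junction)
    G3B = GeneModel("g3b", "chr2", 5000, 6600, "+",
                    exon_starts=(5000, 6300), exon_ends=(5300, 6600),
                    cds_start=5000, cds_end=6600)

    def _candidate(self, g3, bp3):
        svs = SVS("chr1", 1500, 1501, "chr2", bp3, bp3 + 1,
                  "inter_translocation", 12)
        return FusionCandidate("g5", g3.gene_id, svs, 12)

    def test_phase_matched_junction_in_frame(self):
        # retained 5' CDS 300; lost 3' CDS 300 -> phases agree
        out = predict_fusion_transcript(self._candidate(self.G3B, 6000),
                                        genes_by_id([self.G5, self.G3B]))
        assert out.predicted_frame == "in_frame"
        assert out.fusion_exons == ((1,), (2,))

    def test_phase_mismatch_frameshift(self):
        # lost 3' CDS 301 -> junction shifts the downstream frame
        out = predict_fusion_transcript(self._candidate(self.G3A, 6000),
                                        genes_by_id([self.G5, self.G3A]))
        assert out.predicted_frame == "frameshift"

    def test_breakpoint_before_cds_flagged_non_coding(self):
        g5 = GeneModel("g5", "chr1", 1000, 2300, "+",
                       exon_starts=(1000, 2000), exon_ends=(1300, 2300),
                       cds_start=2100, cds_end=2300)
        svs = SVS("chr1", 1500, 1501, "chr2", 6000, 6001,
                  "inter_translocation", 12)
        out = predict_fusion_transcript(
            FusionCandidate("g5", "g3b", svs, 12),
            genes_by_id([g5, self.G3B]))
        assert out.predicted_frame == "non_coding"

    def test_codon_walk_oracle(self):
        """Translating the fused CDS confirms the frame calls: the 3'
        partner's peptide suffix survives only for in-frame junctions."""
        from Bio.Seq import Seq

        seq = ["A"] * 8000
        seq[1000:1300] = list("GCT" * 100)   # 5' exon 1: poly-Ala
        for g3, frame in ((self.G3B, "in_frame"), (self.G3A, "frameshift")):
            # fill both 3' exons with poly-Asp codons in CDS frame
            cds = []
            for s, e in g3.cds_intervals():
                cds.extend(range(s, e))
            for i, p in enumerate(cds):
                seq[p] = "GAT"[i % 3]
            genome = "".join(seq)
            out = predict_fusion_transcript(self._candidate(g3, 6000),
                                            genes_by_id([self.G5, g3]))
            assert out.predicted_frame == frame
            # walk the fused sequence codon by codon
            lost3 = 300 if g3 is self.G3B else 301
            fused = genome[1000:1300] + "".join(
                genome[p] for p in cds[lost3:])
            protein = str(Seq(fused[:len(fused) - len(fused) % 3]).translate())
            if frame == "in_frame":
                assert protein == "A" * 100 + "D" * ((len(fused) - 300) // 3)
            else:
                assert "D" not in protein[100:]


class TestSummaries:
    def test_per_type_counts_and_total(self):
        per_sample = {
            "s1": [_svs(1000, 600_000), _svs(5_000_000, 5_600_000),
                   SVS("chr1", 1, 2, "chr2", 5, 6, "inter_translocation",
                       12)],
            "s2": [_svs(1000, 600_000)],
        }
        df = summarize_sv_counts(per_sample, {"s1": "DGC", "s2": "IGC"})
        s1 = df[df["sample"] == "s1"].iloc[0]
        assert s1["deletion"] == 2 and s1["inter_translocation"] == 1
        assert s1["total"] == 3

    def test_published_class_means_sum_to_totals(self):
        from gcprofiler.reference import SV_CLASS_MEANS

        assert total_from_class_means(SV_CLASS_MEANS["DGC"]) == 552
        assert total_from_class_means(SV_CLASS_MEANS["IGC"]) == 664

    def test_empty_cohort_zeroes(self):
        df = summarize_sv_counts({}, {})
        assert len(df) == 0
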