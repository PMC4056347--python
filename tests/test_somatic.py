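"""Somatic filter cascade, consequence annotation, mutation rate and
substitution spectrum."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcprofiler.genes import GeneModel
from gcprofiler.somatic import (annotate_table, annotate_variant,
                                filter_somatic, mutation_rate,
                                mutation_spectrum)
from gcprofiler.simulate import (SimConfig, blood_pileup, random_genome,
                                 simulate_variant_tables, variant_id)

COLS = ["chrom", "pos", "ref", "alt", "vtype", "depth", "alt_reads",
        "call_quality", "uniquely_mapped", "detected_by"]


def _call(chrom="chr1", pos=100, ref="A", alt="T", vtype="SNV", depth=30,
          alt_reads=10, qual=60.0, unique=True, det=("WGS", "WES")):
    return dict(zip(COLS, (chrom, pos, ref, alt, vtype, depth, alt_reads,
                           qual, unique, frozenset(det))))


def _table(*calls):
    return pd.DataFrame([_call(**c) if isinstance(c, dict) else c
                         for c in calls], columns=COLS)


EMPTY_BLOOD = pd.DataFrame(columns=COLS)


class TestCascade:
    def test_depth_and_quality_gate(self):
        tumor = _table({"pos": 10, "depth": 4}, {"pos": 20, "depth": 250},
                       {"pos": 30, "qual": 10.0}, {"pos": 40})
        out, audit = filter_somatic(tumor, EMPTY_BLOOD)
        assert audit.removed["depth_quality"] == 3
        assert list(out["pos"]) == [40]

    def test_blood_call_subtraction_on_position_and_allele(self):
        tumor = _table({"pos": 10, "alt": "T"}, {"pos": 20, "alt": "G"})
        blood = _table({"pos": 10, "alt": "T"}, {"pos": 20, "alt": "C"})
        out, audit = filter_somatic(tumor, blood)
        assert audit.removed["in_blood_calls"] == 1
        assert list(out["pos"]) == [20]

    def test_blood_pileup_ratio_filter(self):
        tumor = _table({"pos": 10}, {"pos": 20}, {"pos": 30}, {"pos": 40})
        pileup = pd.DataFrame([
            {"chrom": "chr1", "pos": 10, "depth": 10, "alt_ratio": 0.25},
            {"chrom": "chr1", "pos": 20, "depth": 2, "alt_ratio": 0.5},
            {"chrom": "chr1", "pos": 30, "depth": 10, "alt_ratio": 0.1},
        ])  # pos 40 missing from pileup -> treated as depth 0, warned
        out, audit = filter_somatic(tumor, EMPTY_BLOOD, pileup)
        assert audit.removed["blood_pileup_ratio"] == 1
        assert audit.n_missing_pileup == 1
        assert list(out["pos"]) == [20, 30, 40]

    def test_unique_mapping_required(self):
        tumor = _table({"pos": 10, "unique": False}, {"pos": 20})
        out, audit = filter_somatic(tumor, EMPTY_BLOOD)
        assert audit.removed["not_uniquely_mapped"] == 1
        assert list(out["pos"]) == [20]

    def test_duplicated_region_needs_both_platforms(self):
        dup = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1000}])
        tumor = _table({"pos": 10, "det": ("WGS",)},
                       {"pos": 20, "det": ("WGS", "WES")},
                       {"pos": 2000, "det": ("WGS",)})
        out, audit = filter_somatic(tumor, EMPTY_BLOOD, dup_regions=dup)
        assert audit.removed["dup_region_single_platform"] == 1
        assert list(out["pos"]) == [20, 2000]

    def test_known_variant_subtraction(self):
        tumor = _table({"pos": 10, "alt": "T"}, {"pos": 20, "alt": "T"})
        known = [{("chr1", 10, "A", "T")}]
        out, audit = filter_somatic(tumor, EMPTY_BLOOD,
                                    known_variant_sets=known)
        assert audit.removed["known_variant"] == 1
        assert list(out["pos"]) == [20]

    def test_counts_conserve_and_decrease(self):
        tumor = _table({"pos": 10, "depth": 4}, {"pos": 20, "unique": False},
                       {"pos": 30}, {"pos": 40})
        out, audit = filter_somatic(tumor, EMPTY_BLOOD)
        assert sum(audit.removed.values()) + audit.n_surviving == audit.n_input
        assert all(v >= 0 for v in audit.removed.values())

    def test_surviving_set_independent_of_input_order(self, rng):
        tumor = _table(*({"pos": int(p), "depth": int(d)}
                         for p, d in zip(range(10, 200, 10),
                                         rng.integers(3, 60, 19))))
        blood = _table({"pos": 50}, {"pos": 90})
        out1, _ = filter_somatic(tumor, blood)
        shuffled = tumor.sample(frac=1.0, random_state=1)
        out2, _ = filter_somatic(shuffled, blood)
        assert set(out1["pos"]) == set(out2["pos"])

    def test_recovery_on_synthetic_tables(self, base_config, genes, genome):
        # default noise-free tables: every injected somatic call passing
        # the depth/quality gate survives; no germline call survives
        tumor, blood, truth = simulate_variant_tables(base_config, genes,
                                                      genome)
        out, _ = filter_somatic(tumor, blood, blood_pileup(blood))
        ids = {variant_id(c, p, r, a) for c, p, r, a in zip(
            out["chrom"], out["pos"], out["ref"], out["alt"])}
        expected = {
            variant_id(r.chrom, r.pos, r.ref, r.alt)
            for r in tumor.itertuples(index=False)
            if variant_id(r.chrom, r.pos, r.ref, r.alt)
            in truth.somatic_variant_ids
            and 5 <= r.depth <= 200 and r.call_quality >= 20}
        assert ids == expected
        assert not ids & truth.germline_variant_ids


# hand-built two-exon genes on a designed sequence
PLUS_GENE = GeneModel("gplus", "chrT", 10, 90, "+",
                      exon_starts=(10, 60), exon_ends=(40, 90),
                      cds_start=10, cds_end=90)
MINUS_GENE = GeneModel("gminus", "chrT", 110, 190, "-",
                       exon_starts=(110, 160), exon_ends=(140, 190),
                       cds_start=110, cds_end=190)


def _designed_genome():
    seq = list("A" * 250)
    seq[10:13] = "AAA"   # Lys codon at CDS offsets 0-2
    seq[13:16] = "TAT"   # Tyr codon at CDS offsets 3-5
    # minus-strand gene: last codon in genomic order is the first codon
    # of the transcript; 'TTT' reads AAA (Lys) on the coding strand
    seq[187:190] = "TTT"
    return {"chrT": "".join(seq)}


class TestAnnotation:
    def test_synonymous_third_position(self):
        genome = _designed_genome()
        gid, cons = annotate_variant("chrT", 13, "A", "G", "SNV",
                                     [PLUS_GENE], genome)  # AAA -> AAG
        assert (gid, cons) == ("gplus", "synonymous")

    def test_missense(self):
        genome = _designed_genome()
        gid, cons = annotate_variant("chrT", 11, "A", "C", "SNV",
                                     [PLUS_GENE], genome)  # AAA -> ACA
        assert (gid, cons) == ("gplus", "nonsynonymous")

    def test_nonsense(self):
        genome = _designed_genome()
        # TAT (Tyr) -> TAA (stop) at the codon's third base (pos 16)
        gid, cons = annotate_variant("chrT", 16, "T", "A", "SNV",
                                     [PLUS_GENE], genome)
        assert (gid, cons) == ("gplus", "nonsense")

    def test_splice_donor_first_intronic_base(self):
        gid, cons = annotate_variant("chrT", 41, "A", "G", "SNV",
                                     [PLUS_GENE], _designed_genome())
        assert (gid, cons) == ("gplus", "splice_site")

    def test_frameshift_two_base_deletion(self):
        gid, cons = annotate_variant("chrT", 15, "ATA", "A", "DEL",
                                     [PLUS_GENE], _designed_genome())
        assert (gid, cons) == ("gplus", "frameshift")

    def test_inframe_three_base_deletion(self):
        gid, cons = annotate_variant("chrT", 15, "ATAT", "A", "DEL",
                                     [PLUS_GENE], _designed_genome())
        assert (gid, cons) == ("gplus", "inframe_indel")

    def test_minus_strand_synonymous(self):
        genome = _designed_genome()
        # genomic T>C at pos0 187 is coding-strand A>G at the Lys codon's
        # third position: AAA -> AAG, synonymous
        gid, cons = annotate_variant("chrT", 188, "T", "C", "SNV",
                                     [MINUS_GENE], genome)
        assert (gid, cons) == ("gminus", "synonymous")

    def test_intergenic_is_noncoding(self):
        gid, cons = annotate_variant("chrT", 240, "A", "T", "SNV",
                                     [PLUS_GENE, MINUS_GENE],
                                     _designed_genome())
        assert gid is None and cons == "noncoding"

    def test_table_annotation_matches_per_variant(self, base_config, genes,
                                                  genome):
        tumor, _, _ = simulate_variant_tables(base_config, genes, genome)
        sub = tumor.head(50)
        ann = annotate_table(sub, genes, genome)
        for r in ann.itertuples(index=False):
            g, c = annotate_variant(r.chrom, int(r.pos), r.ref, r.alt,
                                    r.vtype, genes, genome)
            assert (r.gene_id, r.consequence) == (g, c)


class TestMutationRate:
    def test_simple_rate(self):
        muts = pd.DataFrame({"chrom": ["chr1"] * 50,
                             "pos": np.arange(1, 51) * 1000})
        mask = pd.DataFrame([{"chrom": "chr1", "start": 0,
                              "end": 10_000_000}])
        assert mutation_rate(muts, mask) == pytest.approx(5.0)

    def test_zero_mutations(self):
        muts = pd.DataFrame({"chrom": [], "pos": []})
        mask = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1000}])
        assert mutation_rate(muts, mask) == 0.0

    def test_empty_mask_rejected(self):
        muts = pd.DataFrame({"chrom": ["chr1"], "pos": [5]})
        with pytest.raises(ValueError, match="mask"):
            mutation_rate(muts, pd.DataFrame(columns=["chrom", "start",
                                                      "end"]))

    def test_estimate_unbiased_over_seeds(self, genes, genome):
        # injected rate recovered within the Poisson sampling band
        rate = 100.0
        mask = pd.DataFrame([{"chrom": g.chrom, "start": s, "end": e}
                             for g in genes for s, e in g.cds_intervals()])
        mask_mb = (mask["end"] - mask["start"]).sum() / 1e6
        estimates = []
        for seed in range(100):
            cfg = SimConfig(seed=seed + 500, genome_length=10_000_000,
                            germline_rate=0.0, somatic_rate=rate)
            tumor, _, _ = simulate_variant_tables(cfg, genes, genome)
            estimates.append(mutation_rate(tumor, mask))
        lam = rate * mask_mb
        se_rate = np.sqrt(lam / 100) / mask_mb
        assert np.mean(estimates) == pytest.approx(rate, abs=4 * se_rate)


class TestSpectrum:
    def test_strand_collapse_c_to_t(self):
        snvs = pd.DataFrame({"ref": ["C", "G", "G"], "alt": ["T", "A", "A"]})
        spec = mutation_spectrum(snvs)
        assert spec["C>T"] == 1.0

    def test_uniform_over_twelve_raw_types(self):
        rows = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        spec = mutation_spectrum(pd.DataFrame(rows, columns=["ref", "alt"]))
        assert np.allclose(spec.values, 1 / 6)

    def test_purine_complement_collapse(self):
        spec = mutation_spectrum(pd.DataFrame({"ref": ["A"], "alt": ["C"]}))
        assert spec["T>G"] == 1.0

    def test_empty_flagged(self):
        spec = mutation_spectrum(pd.DataFrame({"ref": [], "alt": []}))
        assert spec.attrs["empty"]
        assert (spec == 0).all()

    @given(st.lists(st.sampled_from(
        [(r, a) for r in "ACGT" for a in "ACGT" if r != a]),
        min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_fractions_sum_to_one(self, subs):
        spec = mutation_spectrum(pd.DataFrame(subs, columns=["ref", "alt"]))
        assert spec.sum() == pytest.approx(1.0, abs=1e-12)
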