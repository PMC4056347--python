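"""Somatic SNV/indel filtering cascade, consequence annotation, mutation
rate and substitution spectrum.

The cascade takes paired tumor/blood call tables and removes, in order:
calls outside the depth window [5, 200] or below call quality 20; calls
also present in the blood call set (position + alleles); calls where the
blood pileup shows depth >= 3 and alt-allele ratio >= 0.2; calls not
uniquely mapped; calls inside >=90%-identity duplicated regions unless
detected by both WGS and WES; and calls present in known-variant sets
(dbSNP-style / panel-of-normals-style exclusion lists). Each stage's
removal count is logged; the surviving set is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genes import GeneModel

DEPTH_MIN, DEPTH_MAX = 5, 200
CALL_QUALITY_MIN = 20.0
BLOOD_PILEUP_MIN_DEPTH = 3
BLOOD_ALT_RATIO_MIN = 0.2
CDS_MASK_MIN_DEPTH = 5

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CASCADE_STAGES = (
    "depth_quality", "in_blood_calls", "blood_pileup_ratio",
    "not_uniquely_mapped", "dup_region_single_platform", "known_variant",
)


@dataclass
class CascadeAudit:
    n_input: int
    removed: dict[str, int]
    n_surviving: int
    n_missing_pileup: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("surviving", self.n_surviving))
        return pd.DataFrame(rows, columns=["stage", "count"])


def _interval_tree(regions: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if regions is None or len(regions) == 0:
        return trees
    for r in regions.itertuples(index=False):
        trees.setdefault(str(r.chrom), IntervalTree()).addi(int(r.start),
                                                            int(r.end))
    return trees


def _in_regions(trees: dict[str, IntervalTree], chrom: str, pos0: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps_point(pos0))


def filter_somatic(tumor_calls: pd.DataFrame,
                   blood_calls: pd.DataFrame,
                   blood_pileup: pd.DataFrame | None = None,
                   dup_regions: pd.DataFrame | None = None,
                   known_variant_sets: Sequence[set] = (),
                   ) -> tuple[pd.DataFrame, CascadeAudit]:
    """Run the somatic filter cascade; returns survivors + audit counts.

    ``known_variant_sets`` are sets of (chrom, pos, ref, alt) keys.
    Tumor positions absent from the pileup are treated as blood depth 0
    (the pileup stage passes) and counted as warnings.
    """
    df = tumor_calls.reset_index(drop=True)
    removed: dict[str, int] = {}
    n_input = len(df)

    # stage 1: depth window and call quality
    keep = (df["depth"].between(DEPTH_MIN, DEPTH_MAX)
            & (df["call_quality"] >= CALL_QUALITY_MIN))
    removed["depth_quality"] = int((~keep).sum())
    df = df[keep]

    # stage 2: subtract blood calls on position + alleles
    blood_keys = set(zip(blood_calls["chrom"], blood_calls["pos"],
                         blood_calls["ref"], blood_calls["alt"]))
    if "called" in blood_calls.columns:
        blood_keys = set(
            zip(blood_calls.loc[blood_calls["called"], "chrom"],
                blood_calls.loc[blood_calls["called"], "pos"],
                blood_calls.loc[blood_calls["called"], "ref"],
                blood_calls.loc[blood_calls["called"], "alt"]))
    keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
    keep = np.array([k not in blood_keys for k in keys], dtype=bool)
    removed["in_blood_calls"] = int((~keep).sum())
    df = df[keep]

    # stage 3: blood pileup evidence of the alt allele
    n_missing = 0
    if blood_pileup is not None and len(blood_pileup) > 0:
        pmap = {(c, p): (d, r) for c, p, d, r in zip(
            blood_pileup["chrom"], blood_pileup["pos"],
            blood_pileup["depth"], blood_pileup["alt_ratio"])}
        flags = []
        for c, p in zip(df["chrom"], df["pos"]):
            if (c, p) not in pmap:
                n_missing += 1
                flags.append(True)
                continue
            d, r = pmap[(c, p)]
            flags.append(not (d >= BLOOD_PILEUP_MIN_DEPTH
                              and r >= BLOOD_ALT_RATIO_MIN))
        keep = np.array(flags, dtype=bool)
    else:
        n_missing = len(df)
        keep = np.ones(len(df), dtype=bool)
    removed["blood_pileup_ratio"] = int((~keep).sum())
    df = df[keep]

    # stage 4: unique mapping
    keep = df["uniquely_mapped"].astype(bool).values
    removed["not_uniquely_mapped"] = int((~keep).sum())
    df = df[keep]

    # stage 5: duplicated regions require dual-platform detection
    trees = _interval_tree(dup_regions)
    if trees:
        keep = np.array([
            (not _in_regions(trees, c, p - 1))
            or (set(det) >= {"WGS", "WES"})
            for c, p, det in zip(df["chrom"], df["pos"], df["detected_by"])],
            dtype=bool)
    else:
        keep = np.ones(len(df), dtype=bool)
    removed["dup_region_single_platform"] = int((~keep).sum())
    df = df[keep]

    # stage 6: known-variant subtraction
    known: set = set()
    for s in known_variant_sets:
        known |= set(s)
    if known:
        keep = np.array([
            (c, p, ref, alt) not in known
            for c, p, ref, alt in zip(df["chrom"], df["pos"], df["ref"],
                                      df["alt"])], dtype=bool)
    else:
        keep = np.ones(len(df), dtype=bool)
    removed["known_variant"] = int((~keep).sum())
    df = df[keep].reset_index(drop=True)

    audit = CascadeAudit(n_input=n_input, removed=removed,
                         n_surviving=len(df), n_missing_pileup=n_missing)
    return df, audit


# ---------------------------------------------------------------------------
# consequence annotation

CONSEQUENCES = ("synonymous", "nonsynonymous", "nonsense", "splice_site",
                "frameshift", "inframe_indel", "noncoding")


def annotate_variant(chrom: str, pos: int, ref: str, alt: str, vtype: str,
                     gene_models: Sequence[GeneModel],
                     genome: dict[str, str] | None = None,
                     ) -> tuple[str | None, str]:
    """(gene_id, consequence) for one variant; pos is 1-based.

    SNV consequences are found by translating the affected codon on the
    coding strand (requires the genome sequence); indels in CDS are
    frameshift when length % 3 != 0, inframe otherwise. Splice sites are
    the 2 intronic bases flanking exon boundaries. Variants outside any
    gene are noncoding.
    """
    pos0 = pos - 1
    for gene in gene_models:
        if gene.chrom != chrom or not (gene.start - 2 <= pos0 < gene.end + 2):
            continue
        if pos0 in gene.splice_site_positions():
            return gene.gene_id, "splice_site"
        if not gene.contains(pos0):
            continue
        if vtype in ("INS", "DEL"):
            if gene.in_cds(pos0):
                indel_len = abs(len(ref) - len(alt))
                return gene.gene_id, ("frameshift" if indel_len % 3
                                      else "inframe_indel")
            return gene.gene_id, "noncoding"
        if gene.in_cds(pos0):
            if genome is None:
                raise ValueError("genome sequence required for CDS SNV "
                                 "consequence annotation")
            return gene.gene_id, _snv_consequence(genome, gene, pos0, alt)
        return gene.gene_id, "noncoding"
    return None, "noncoding"


_CODON_AA: dict[str, str] = {}


def codon_aa(codon: str) -> str:
    """Standard-table amino acid for a codon (memoized)."""
    if not _CODON_AA:
        from itertools import product

        for c in product("ACGT", repeat=3):
            s = "".join(c)
            _CODON_AA[s] = str(Seq(s).translate())
    return _CODON_AA[codon]


def _snv_consequence(genome: dict[str, str], gene: GeneModel, pos0: int,
                     alt: str) -> str:
    off = gene.cds_offset(pos0)
    cds_pos = gene.cds_genomic_positions()
    codon_idx = off // 3
    codon_pos = cds_pos[codon_idx * 3: codon_idx * 3 + 3]
    if len(codon_pos) < 3:  # trailing partial codon
        return "noncoding"
    seq = genome[gene.chrom]
    codon = "".join(seq[p] if gene.strand == "+" else _COMPLEMENT[seq[p]]
                    for p in codon_pos)
    alt_coding = alt if gene.strand == "+" else _COMPLEMENT[alt]
    mut = list(codon)
    mut[off % 3] = alt_coding
    aa_ref = codon_aa(codon)
    aa_alt = codon_aa("".join(mut))
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "nonsynonymous"


def annotate_table(variants: pd.DataFrame, gene_models: Sequence[GeneModel],
                   genome: dict[str, str] | None = None) -> pd.DataFrame:
    """Vectorized annotation: gene lookup via an interval tree, splice
    sites precomputed per gene."""
    trees: dict[str, IntervalTree] = {}
    by_id = {g.gene_id: g for g in gene_models}
    splice: dict[str, set[int]] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - 2, g.end + 2, g.gene_id)
        splice[g.gene_id] = g.splice_site_positions()

    def one(chrom, pos, ref, alt, vtype):
        pos0 = pos - 1
        tree = trees.get(chrom)
        hits = sorted(iv.data for iv in tree.at(pos0)) if tree else []
        for gid in hits:
            gene = by_id[gid]
            if pos0 in splice[gid]:
                return gid, "splice_site"
            if not gene.contains(pos0):
                continue
            if vtype in ("INS", "DEL"):
                if gene.in_cds(pos0):
                    return gid, ("frameshift"
                                 if abs(len(ref) - len(alt)) % 3
                                 else "inframe_indel")
                return gid, "noncoding"
            if gene.in_cds(pos0):
                if genome is None:
                    raise ValueError("genome sequence required for CDS SNV "
                                     "consequence annotation")
                return gid, _snv_consequence(genome, gene, pos0, alt)
            return gid, "noncoding"
        return None, "noncoding"

    out = variants.copy()
    res = [one(c, int(p), r, a, v) for c, p, r, a, v in zip(
        out["chrom"], out["pos"], out["ref"], out["alt"], out["vtype"])]
    out["gene_id"] = [g for g, _ in res]
    out["consequence"] = [c for _, c in res]
    return out


def is_nonsynonymous(consequence: pd.Series) -> pd.Series:
    """Nonsense counts within the nonsynonymous class for scoring."""
    return consequence.isin(["nonsynonymous", "nonsense"])


# ---------------------------------------------------------------------------
# mutation rate and spectrum

def mutation_rate(somatic_variants: pd.DataFrame,
                  cds_mask: pd.DataFrame) -> float:
    """Mutations (SNVs + small indels) per Mb of sufficiently covered CDS.

    The mask is the set of CDS intervals with read depth >= 5; only
    variants inside the mask are counted.
    """
    if cds_mask is None or len(cds_mask) == 0:
        raise ValueError("empty CDS coverage mask")
    mask_bases = int((cds_mask["end"] - cds_mask["start"]).sum())
    if mask_bases <= 0:
        raise ValueError("CDS coverage mask has zero length")
    trees = _interval_tree(cds_mask)
    n = sum(_in_regions(trees, c, p - 1)
            for c, p in zip(somatic_variants["chrom"], somatic_variants["pos"]))
    return n / (mask_bases / 1e6)


def mutation_spectrum(somatic_snvs: pd.DataFrame) -> pd.Series:
    """Fractions over the six pyrimidine-referenced substitution classes.

    Purine-reference substitutions are collapsed onto their reverse
    complement (G>A counts as C>T, etc.). Empty input yields an all-zero
    vector with ``attrs['empty'] = True``.
    """
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    snvs = somatic_snvs
    if "vtype" in snvs.columns:
        snvs = snvs[snvs["vtype"] == "SNV"]
    for ref, alt in zip(snvs["ref"], snvs["alt"]):
        if ref in "GA":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    total = sum(counts.values())
    frac = pd.Series(
        {k: (v / total if total else 0.0) for k, v in counts.items()},
        name="fraction")
    frac.attrs["empty"] = total == 0
    frac.attrs["n_snvs"] = total
    return frac
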