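"""Structural-variation signals from discordant read pairs.

An SVS (structural variation signal) is a cluster of more than three
(i.e. >= 4) uniquely and discordantly mapped read pairs supporting one
rearrangement. Pairs are typed by chromosome, orientation and span
against the library insert distribution; same-type pairs whose
corresponding ends lie within a join distance (default 400 bp, the same
radius used for SVS equivalence) are single-linkage clustered. Somatic
SVSs are tumor SVSs with no blood SVS (of any type) whose breakpoints
both lie within 400 bp. Gene breakage is an SVS breakpoint falling
within a gene; interchromosomal SVSs connecting two distinct genes with
more than 10 (>= 11) supporting pairs are fusion candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genes import GeneModel

SV_TYPES = ("insertion", "deletion", "inversion", "intra_translocation",
            "inter_translocation")
MIN_SVS_SUPPORT = 4       # "more than three" read pairs
MIN_FUSION_SUPPORT = 11   # "above 10" read pairs
EQUIVALENCE_RADIUS = 400  # bp; also the default clustering join distance


@dataclass(frozen=True)
class LibraryStats:
    median_insert: float = 400.0
    mad: float = 40.0
    k: float = 3.0
    max_deletion_span: float = 1_000_000.0


@dataclass(frozen=True)
class SVS:
    chrom1: str
    bp1_start: int
    bp1_end: int
    chrom2: str
    bp2_start: int
    bp2_end: int
    sv_type: str
    n_support: int

    def __post_init__(self) -> None:
        if self.n_support < MIN_SVS_SUPPORT:
            raise ValueError(
                f"an SVS needs >= {MIN_SVS_SUPPORT} supporting pairs, "
                f"got {self.n_support}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")

    @property
    def bp1_mid(self) -> float:
        return (self.bp1_start + self.bp1_end) / 2.0

    @property
    def bp2_mid(self) -> float:
        return (self.bp2_start + self.bp2_end) / 2.0


@dataclass(frozen=True)
class FusionCandidate:
    gene5: str
    gene3: str
    svs: SVS
    n_support: int
    predicted_frame: str | None = None  # in_frame | frameshift | non_coding
    fusion_exons: tuple[tuple[int, ...], tuple[int, ...]] | None = None


def classify_pair(chrom1: str, pos1: int, strand1: str,
                  chrom2: str, pos2: int, strand2: str,
                  stats: LibraryStats = LibraryStats()) -> str | None:
    """Discordance class for one read pair (None = concordant).

    Mate order must be normalized (chrom1 <= chrom2, then pos1 <= pos2).
    Different chromosomes -> inter_translocation; same-strand ->
    inversion; convergent (+/-) pairs by span against median +/- k*MAD:
    longer -> deletion, shorter -> insertion, beyond the maximum span ->
    intra_translocation; divergent (-/+) orientation is everted and also
    typed intra_translocation.
    """
    if (chrom1, pos1) > (chrom2, pos2):
        raise ValueError("mate order not normalized "
                         f"({chrom1}:{pos1} > {chrom2}:{pos2})")
    if chrom1 != chrom2:
        return "inter_translocation"
    if strand1 == strand2:
        return "inversion"
    span = pos2 - pos1
    if strand1 == "-":  # divergent / everted
        return "intra_translocation"
    if span > stats.max_deletion_span:
        return "intra_translocation"
    if span > stats.median_insert + stats.k * stats.mad:
        return "deletion"
    if span < stats.median_insert - stats.k * stats.mad:
        return "insertion"
    return None


def _classify_table(pairs: pd.DataFrame, stats: LibraryStats) -> pd.Series:
    return pd.Series(
        [classify_pair(c1, p1, s1, c2, p2, s2, stats)
         for c1, p1, s1, c2, p2, s2 in zip(
             pairs["chrom1"], pairs["pos1"], pairs["strand1"],
             pairs["chrom2"], pairs["pos2"], pairs["strand2"])],
        index=pairs.index, dtype=object)


def cluster_svs(pairs: pd.DataFrame,
                stats: LibraryStats = LibraryStats(),
                join_distance: int = EQUIVALENCE_RADIUS,
                min_support: int = MIN_SVS_SUPPORT) -> list[SVS]:
    """Single-linkage clustering of discordant pairs into SVSs.

    Only uniquely mapped, discordant pairs participate. Two same-class
    pairs on the same chromosome pair join when both their first ends
    and their second ends are within the join distance. Clusters with at
    least ``min_support`` members are emitted, deterministically ordered
    by (chrom1, bp1_start, chrom2, bp2_start, sv_type).
    """
    df = pairs[pairs["uniquely_mapped"].astype(bool)].copy()
    if len(df) == 0:
        return []
    df["sv_class"] = _classify_table(df, stats)
    df = df[df["sv_class"].notna()]
    out: list[SVS] = []
    for (cls, c1, c2), grp in df.groupby(["sv_class", "chrom1", "chrom2"],
                                         sort=True):
        g = grp.sort_values(["pos1", "pos2"], kind="stable")
        p1 = g["pos1"].to_numpy()
        p2 = g["pos2"].to_numpy()
        n = len(g)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        # sorted by pos1: only nearby-in-pos1 pairs can join
        for i in range(n):
            for j in range(i + 1, n):
                if p1[j] - p1[i] > join_distance:
                    break
                if abs(p2[j] - p2[i]) <= join_distance:
                    union(i, j)
        members: dict[int, list[int]] = {}
        for i in range(n):
            members.setdefault(find(i), []).append(i)
        for idxs in members.values():
            if len(idxs) < min_support:
                continue
            out.append(SVS(
                chrom1=c1, bp1_start=int(p1[idxs].min()),
                bp1_end=int(p1[idxs].max()) + 1,
                chrom2=c2, bp2_start=int(p2[idxs].min()),
                bp2_end=int(p2[idxs].max()) + 1,
                sv_type=cls, n_support=len(idxs)))
    out.sort(key=lambda s: (s.chrom1, s.bp1_start, s.chrom2, s.bp2_start,
                            s.sv_type))
    return out


def svs_equal(a: SVS, b: SVS, radius: int = EQUIVALENCE_RADIUS) -> bool:
    """Two SVSs are equal when both breakpoints are within ``radius`` bp
    (inclusive); type is not compared."""
    return (a.chrom1 == b.chrom1 and a.chrom2 == b.chrom2
            and abs(a.bp1_mid - b.bp1_mid) <= radius
            and abs(a.bp2_mid - b.bp2_mid) <= radius)


def somatic_svs(tumor_svs: Sequence[SVS], blood_svs: Sequence[SVS],
                radius: int = EQUIVALENCE_RADIUS) -> list[SVS]:
    """Tumor SVSs not found (within the equivalence radius) in blood."""
    return [t for t in tumor_svs
            if not any(svs_equal(t, b, radius) for b in blood_svs)]


def _gene_trees(genes: Sequence[GeneModel],
                exonic: bool = False) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        if exonic:
            for s, e in g.exons():
                tree.addi(s, e, g.gene_id)
        else:
            tree.addi(g.start, g.end, g.gene_id)
    return trees


def _overlap_genes(trees: Mapping[str, IntervalTree], chrom: str,
                   start: int, end: int) -> set[str]:
    tree = trees.get(chrom)
    if tree is None:
        return set()
    return {iv.data for iv in tree.overlap(start, end)}


def gene_breakage(svs_list: Sequence[SVS], genes: Sequence[GeneModel],
                  exon_filter: bool = False) -> set[str]:
    """Genes with an SVS breakpoint inside their transcribed span.

    With ``exon_filter`` on, SVSs with neither breakpoint overlapping any
    exon are excluded before tallying (intronic/intergenic signals are
    then ignored; off by default so intronic breakpoints still count as
    breakage, matching per-sample alteration reporting).
    """
    gene_tr = _gene_trees(genes, exonic=False)
    exon_tr = _gene_trees(genes, exonic=True) if exon_filter else None
    impaired: set[str] = set()
    for s in svs_list:
        if exon_filter:
            hits = (_overlap_genes(exon_tr, s.chrom1, s.bp1_start, s.bp1_end)
                    | _overlap_genes(exon_tr, s.chrom2, s.bp2_start, s.bp2_end))
            if not hits:
                continue
        impaired |= _overlap_genes(gene_tr, s.chrom1, s.bp1_start, s.bp1_end)
        impaired |= _overlap_genes(gene_tr, s.chrom2, s.bp2_start, s.bp2_end)
    return impaired


def call_fusions(svs_list: Sequence[SVS], genes: Sequence[GeneModel],
                 min_support: int = MIN_FUSION_SUPPORT) -> list[FusionCandidate]:
    """Interchromosomal SVSs connecting two distinct genes with enough
    supporting pairs."""
    gene_tr = _gene_trees(genes, exonic=False)
    out: list[FusionCandidate] = []
    for s in svs_list:
        if s.sv_type != "inter_translocation" or s.n_support < min_support:
            continue
        g1 = _overlap_genes(gene_tr, s.chrom1, s.bp1_start, s.bp1_end)
        g2 = _overlap_genes(gene_tr, s.chrom2, s.bp2_start, s.bp2_end)
        for a in sorted(g1):
            for b in sorted(g2):
                if a != b:
                    out.append(FusionCandidate(
                        gene5=a, gene3=b, svs=s, n_support=s.n_support))
    return out


def _retained_5p(gene: GeneModel, bp: int) -> tuple[list[int], int]:
    """Exon indices (1-based, transcript order) retained upstream of the
    breakpoint in the 5' partner, plus retained CDS length."""
    exons = gene.exons()
    order = range(len(exons)) if gene.strand == "+" else range(len(exons) - 1, -1, -1)
    retained, cds_len = [], 0
    for rank, i in enumerate(order, start=1):
        s, e = exons[i]
        upstream = e <= bp if gene.strand == "+" else s >= bp
        if upstream:
            retained.append(rank)
            cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
            if cs < ce:
                cds_len += ce - cs
        else:
            # partial exon truncated at the breakpoint
            if s <= bp < e if gene.strand == "+" else s < bp <= e:
                cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
                if gene.strand == "+" and cs < min(bp, ce):
                    cds_len += min(bp, ce) - cs
                elif gene.strand == "-" and max(bp, cs) < ce:
                    cds_len += ce - max(bp, cs)
            break
    return retained, cds_len


def _retained_3p(gene: GeneModel, bp: int) -> tuple[list[int], int]:
    """Exon indices retained downstream of the breakpoint in the 3'
    partner, plus the *lost* upstream CDS length (its codon phase)."""
    exons = gene.exons()
    order = range(len(exons)) if gene.strand == "+" else range(len(exons) - 1, -1, -1)
    retained, lost = [], 0
    for rank, i in enumerate(order, start=1):
        s, e = exons[i]
        upstream = e <= bp if gene.strand == "+" else s >= bp
        cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
        if upstream:
            if cs < ce:
                lost += ce - cs
        else:
            retained.append(rank)
            if (s <= bp < e if gene.strand == "+" else s < bp <= e) and cs < ce:
                if gene.strand == "+" and cs < min(bp, ce):
                    lost += min(bp, ce) - cs
                elif gene.strand == "-" and max(bp, cs) < ce:
                    lost += ce - max(bp, cs)
    return retained, lost


def predict_fusion_transcript(candidate: FusionCandidate,
                              genes_by_id: Mapping[str, GeneModel],
                              ) -> FusionCandidate:
    """Retained exons and reading-frame prediction for a fusion.

    The fused transcript keeps the 5' partner's exons upstream of its
    breakpoint and the 3' partner's exons downstream of its breakpoint.
    The junction is in frame when the retained 5' CDS length and the
    lost 3' upstream CDS length agree modulo 3 (the downstream codon
    phase is preserved); otherwise it is a frameshift. A breakpoint
    upstream of the 5' partner's CDS start yields a non-coding flag.
    """
    g5 = genes_by_id[candidate.gene5]
    g3 = genes_by_id[candidate.gene3]
    bp5 = int(candidate.svs.bp1_mid)
    bp3 = int(candidate.svs.bp2_mid)
    ex5, len5 = _retained_5p(g5, bp5)
    ex3, lost3 = _retained_3p(g3, bp3)
    if len5 == 0:
        frame = "non_coding"
    else:
        frame = "in_frame" if (len5 - lost3) % 3 == 0 else "frameshift"
    return FusionCandidate(
        gene5=candidate.gene5, gene3=candidate.gene3, svs=candidate.svs,
        n_support=candidate.n_support, predicted_frame=frame,
        fusion_exons=(tuple(ex5), tuple(ex3)))


def summarize_sv_counts(per_sample_svs: Mapping[str, Sequence[SVS]],
                        sample_types: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample counts by the five SV classes + total, with cohort
    means appended per sample type. total == sum of class counts."""
    rows = []
    for sample, svs_list in sorted(per_sample_svs.items()):
        counts = dict.fromkeys(SV_TYPES, 0)
        for s in svs_list:
            counts[s.sv_type] += 1
        total = sum(counts.values())
        rows.append({"sample": sample, "group": sample_types[sample],
                     **counts, "total": total})
    df = pd.DataFrame(rows)
    if len(df):
        assert (df["total"] == df[list(SV_TYPES)].sum(axis=1)).all()
        means = df.groupby("group")[list(SV_TYPES) + ["total"]].mean()
        means = means.reset_index().assign(sample="mean")
        df = pd.concat([df, means], ignore_index=True)
    return df


def total_from_class_means(class_means: Mapping[str, float]) -> float:
    """Total somatic-SV mean from per-class cohort means; classes must be
    exactly the five SV types."""
    if set(class_means) != set(SV_TYPES):
        raise ValueError(f"expected the classes {SV_TYPES}")
    return float(sum(class_means.values()))


def svs_to_bedpe(svs_list: Sequence[SVS]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom1": s.chrom1, "start1": s.bp1_start, "end1": s.bp1_end,
        "chrom2": s.chrom2, "start2": s.bp2_start, "end2": s.bp2_end,
        "name": s.sv_type, "score": s.n_support,
        "strand1": ".", "strand2": ".",
    } for s in svs_list])
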