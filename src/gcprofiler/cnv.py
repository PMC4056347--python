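"""Copy-number segmentation, classification and alteration integration.

Binned tumor/normal read counts are segmented by a BIC-penalized greedy
merge (a transparent approximation to BIC-seq: a binomial likelihood data
term plus a per-breakpoint penalty lambda, default 100, on fixed 1-kb
bins). Segments are classified by log2 ratio: > 0.2 duplicated, < -0.2
deleted (strict inequalities, so |log2| = 0.2 exactly is neutral); the
array-CGH convention uses +0.152173 / -0.135797 for gain / loss.

Per-gene copy status, the per-gene x per-sample integrated alteration
matrix (SNV / INDEL / CNV loss / CNV gain / SV breakpoint), mutual
exclusivity counting and cross-cohort mutated-gene comparison live here
as well.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel

WGS_LOG2_GAIN = 0.2
WGS_LOG2_LOSS = -0.2
ACGH_LOG2_GAIN = 0.152173
ACGH_LOG2_LOSS = -0.135797
DEFAULT_LAMBDA = 100.0
DEFAULT_BIN_SIZE = 1000

ALTERATION_CATEGORIES = ("SNV", "INDEL", "CNV_loss", "CNV_gain",
                         "SV_breakpoint")


@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    log2_ratio: float
    state: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def _seg_loglik(t: float, n: float) -> float:
    """Binomial log-likelihood of tumor reads among tumor+normal reads
    in one segment, at the segment's MLE proportion."""
    tot = t + n
    if tot == 0 or t == 0 or n == 0:
        return 0.0
    p = t / tot
    return t * np.log(p) + n * np.log(1.0 - p)


def segment_depth_bins(bins: pd.DataFrame,
                       lam: float = DEFAULT_LAMBDA,
                       bin_size: int | None = None) -> list[CNVSegment]:
    """Greedy BIC-penalized merge of adjacent fixed-size count bins.

    ``bins``: chrom, start, end, tumor_count, normal_count on uniform
    bins (non-uniform widths are rejected; a shorter final bin per
    chromosome is allowed). Merging two adjacent segments is accepted
    while it lowers  -2*loglik + lam * n_breakpoints;  the most negative
    delta is merged first, ties to the leftmost. Deterministic.
    """
    df = bins.reset_index(drop=True)
    widths = (df["end"] - df["start"]).to_numpy()
    if bin_size is None:
        bin_size = int(widths.max())
    for chrom, grp in df.groupby("chrom", sort=False):
        w = (grp["end"] - grp["start"]).to_numpy()
        if (w[:-1] != bin_size).any() or w[-1] > bin_size:
            raise ValueError(f"non-uniform bins on {chrom}: expected "
                             f"{bin_size} bp")
    total_t = float(df["tumor_count"].sum())
    total_n = float(df["normal_count"].sum())
    if total_t <= 0 or total_n <= 0:
        raise ValueError("tumor and normal totals must be positive")

    segments: list[CNVSegment] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        t = grp["tumor_count"].to_numpy(dtype=float)
        n = grp["normal_count"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        m = len(grp)
        # doubly linked segment list over bin ranges [lo, hi)
        seg_t = t.copy()
        seg_n = n.copy()
        seg_lo = list(range(m))
        seg_hi = [i + 1 for i in range(m)]
        nxt = list(range(1, m)) + [-1]
        prv = [-1] + list(range(m - 1))
        alive = [True] * m
        ll = [_seg_loglik(seg_t[i], seg_n[i]) for i in range(m)]

        def merge_delta(i: int, j: int) -> float:
            merged = _seg_loglik(seg_t[i] + seg_t[j], seg_n[i] + seg_n[j])
            # delta of (-2*loglik + lam*breakpoints): one breakpoint removed
            return -2.0 * (merged - ll[i] - ll[j]) - lam

        heap: list[tuple[float, int, int]] = []
        for i in range(m - 1):
            heapq.heappush(heap, (merge_delta(i, i + 1), i, i + 1))
        while heap:
            delta, i, j = heapq.heappop(heap)
            if not (alive[i] and alive[j]) or nxt[i] != j:
                continue  # stale entry
            if delta >= 0:
                break
            # merge j into i
            seg_t[i] += seg_t[j]
            seg_n[i] += seg_n[j]
            seg_hi[i] = seg_hi[j]
            ll[i] = _seg_loglik(seg_t[i], seg_n[i])
            alive[j] = False
            nxt[i] = nxt[j]
            if nxt[i] != -1:
                prv[nxt[i]] = i
                heapq.heappush(heap, (merge_delta(i, nxt[i]), i, nxt[i]))
            if prv[i] != -1:
                heapq.heappush(heap, (merge_delta(prv[i], i), prv[i], i))
        i = 0
        while i != -1 and m > 0:
            if alive[i]:
                with np.errstate(divide="ignore"):
                    ratio = ((seg_t[i] / total_t) / (seg_n[i] / total_n)
                             if seg_n[i] > 0 else np.inf)
                    log2r = float(np.log2(ratio)) if ratio > 0 else -np.inf
                segments.append(CNVSegment(
                    chrom=chrom, start=int(starts[seg_lo[i]]),
                    end=int(ends[seg_hi[i] - 1]), log2_ratio=log2r))
            i = nxt[i]
    return segments


def classify_segment(log2_ratio: float, convention: str = "wgs") -> str:
    """Copy state from a log2 ratio.

    wgs: > 0.2 'duplicated', < -0.2 'deleted'; acgh: > +0.152173 'gain',
    < -0.135797 'loss'. Inequalities are strict, so the boundary values
    themselves are neutral.
    """
    if not np.isfinite(log2_ratio):
        raise ValueError(f"log2 ratio must be finite, got {log2_ratio}")
    if convention == "wgs":
        hi, lo, up, down = WGS_LOG2_GAIN, WGS_LOG2_LOSS, "duplicated", "deleted"
    elif convention == "acgh":
        hi, lo, up, down = ACGH_LOG2_GAIN, ACGH_LOG2_LOSS, "gain", "loss"
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if log2_ratio > hi:
        return up
    if log2_ratio < lo:
        return down
    return "neutral"


_CANONICAL_STATE = {"duplicated": "gain", "deleted": "loss",
                    "gain": "gain", "loss": "loss", "neutral": "neutral"}


def classify_segments(segments: Iterable[CNVSegment],
                      convention: str = "wgs") -> list[CNVSegment]:
    """Classify segments and canonicalize states to gain/loss/neutral
    (the labels the gene-level and matrix layers use)."""
    out = []
    for s in segments:
        state = (classify_segment(s.log2_ratio, convention)
                 if np.isfinite(s.log2_ratio)
                 else ("deleted" if s.log2_ratio < 0 else "duplicated"))
        out.append(CNVSegment(s.chrom, s.start, s.end, s.log2_ratio,
                              _CANONICAL_STATE[state]))
    return out


def gene_copy_status(segments: Sequence[CNVSegment],
                     genes: Sequence[GeneModel],
                     min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Per-gene copy state from classified segments.

    A non-neutral state must cover at least ``min_overlap_fraction`` of
    the gene span; when both gain and loss qualify the larger coverage
    wins, exact ties fall back to neutral.
    """
    rows = []
    for g in genes:
        span = g.end - g.start
        cov = {"gain": 0, "loss": 0, "neutral": 0}
        for s in segments:
            if s.chrom != g.chrom:
                continue
            ov = min(g.end, s.end) - max(g.start, s.start)
            if ov > 0 and s.state is not None:
                cov[s.state] += ov
        state = "neutral"
        qual = {k: v for k, v in cov.items()
                if k != "neutral" and v >= min_overlap_fraction * span}
        if qual:
            best = max(qual.values())
            winners = [k for k, v in qual.items() if v == best]
            state = winners[0] if len(winners) == 1 else "neutral"
        rows.append({"gene_id": g.gene_id, "state": state,
                     "gain_bases": cov["gain"], "loss_bases": cov["loss"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# integrated alteration matrix

class AlterationMatrix:
    """Per (gene, sample) sets of alteration categories.

    Long-form storage: one row per (gene, sample, category). The sample
    universe and the DGC/IGC type labels are carried explicitly so genes
    and samples with no alterations still count in denominators.
    """

    def __init__(self, entries: pd.DataFrame,
                 sample_types: Mapping[str, str]):
        self.entries = entries.reset_index(drop=True)
        self.sample_types = dict(sample_types)
        unknown = set(entries["sample"]) - set(self.sample_types)
        if unknown:
            raise ValueError(f"unknown sample ids in call sets: "
                             f"{sorted(unknown)}")
        bad = set(entries["category"]) - set(ALTERATION_CATEGORIES)
        if bad:
            raise ValueError(f"unknown alteration categories: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_types)

    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())

    def categories(self, gene: str, sample: str) -> set[str]:
        sel = self.entries[(self.entries["gene"] == gene)
                           & (self.entries["sample"] == sample)]
        return set(sel["category"])

    def to_table(self, gene: str | None = None) -> pd.DataFrame:
        df = self.entries.copy()
        if gene is not None:
            df = df[df["gene"] == gene]
        df = df.assign(group=df["sample"].map(self.sample_types))
        return df.sort_values(["gene", "sample", "category"],
                              kind="stable").reset_index(drop=True)


def build_alteration_matrix(somatic_variants: pd.DataFrame | None,
                            gene_cnv: pd.DataFrame | None,
                            impaired_genes: pd.DataFrame | None,
                            sample_types: Mapping[str, str],
                            ) -> AlterationMatrix:
    """Union of the three upstream call sets into one matrix.

    ``somatic_variants``: sample, gene_id, vtype (SNV/INS/DEL) rows, one
    per surviving annotated variant (noncoding rows are ignored);
    ``gene_cnv``: sample, gene_id, state (gain/loss/neutral);
    ``impaired_genes``: sample, gene_id rows from SV breakage.
    """
    rows: list[tuple[str, str, str]] = []
    if somatic_variants is not None and len(somatic_variants):
        for r in somatic_variants.itertuples(index=False):
            if getattr(r, "gene_id", None) is None:
                continue
            cons = getattr(r, "consequence", "")
            if cons == "noncoding":
                continue
            cat = "SNV" if r.vtype == "SNV" else "INDEL"
            rows.append((r.gene_id, r.sample, cat))
    if gene_cnv is not None and len(gene_cnv):
        for r in gene_cnv.itertuples(index=False):
            if r.state == "loss":
                rows.append((r.gene_id, r.sample, "CNV_loss"))
            elif r.state == "gain":
                rows.append((r.gene_id, r.sample, "CNV_gain"))
    if impaired_genes is not None and len(impaired_genes):
        for r in impaired_genes.itertuples(index=False):
            rows.append((r.gene_id, r.sample, "SV_breakpoint"))
    entries = (pd.DataFrame(rows, columns=["gene", "sample", "category"])
               .drop_duplicates()
               .sort_values(["gene", "sample", "category"], kind="stable"))
    return AlterationMatrix(entries, sample_types)


@dataclass(frozen=True)
class ExclusivityCounts:
    a_only: int
    b_only: int
    both: int
    neither: int
    both_fraction: float


def mutual_exclusivity(matrix: AlterationMatrix, gene: str,
                       class_a: Iterable[str] = ("SNV", "INDEL"),
                       class_b: Iterable[str] = ("CNV_loss",),
                       ) -> ExclusivityCounts:
    """Partition the sample universe by presence of two alteration
    classes in one gene (e.g. point mutation vs copy loss)."""
    class_a, class_b = set(class_a), set(class_b)
    a_only = b_only = both = neither = 0
    for sample in matrix.samples:
        cats = matrix.categories(gene, sample)
        has_a, has_b = bool(cats & class_a), bool(cats & class_b)
        if has_a and has_b:
            both += 1
        elif has_a:
            a_only += 1
        elif has_b:
            b_only += 1
        else:
            neither += 1
    n = len(matrix.samples)
    return ExclusivityCounts(a_only, b_only, both, neither,
                             both / n if n else 0.0)


@dataclass(frozen=True)
class CohortComparison:
    n_a: int
    n_b: int
    n_common: int
    n_union: int
    pct_common: float


def cohort_compare(genes_a: set[str], genes_b: set[str]) -> CohortComparison:
    """Mutated-gene overlap between two disjoint sample groups."""
    common = genes_a & genes_b
    union = genes_a | genes_b
    n_union = len(union)
    return CohortComparison(
        n_a=len(genes_a), n_b=len(genes_b), n_common=len(common),
        n_union=n_union,
        pct_common=100.0 * len(common) / n_union if n_union else 0.0)


def compare_counts(n_a: int, n_b: int, n_common: int) -> CohortComparison:
    """Inclusion-exclusion from printed per-group counts."""
    n_union = n_a + n_b - n_common
    return CohortComparison(
        n_a=n_a, n_b=n_b, n_common=n_common, n_union=n_union,
        pct_common=100.0 * n_common / n_union if n_union else 0.0)


def mutated_gene_sets(matrix: AlterationMatrix,
                      qualifying: Iterable[str] = ("SNV",),
                      ) -> dict[str, set[str]]:
    """Per sample-group sets of genes with >= 1 qualifying alteration."""
    qualifying = set(qualifying)
    out: dict[str, set[str]] = {}
    df = matrix.entries[matrix.entries["category"].isin(qualifying)]
    for r in df.itertuples(index=False):
        group = matrix.sample_types[r.sample]
        out.setdefault(group, set()).add(r.gene)
    for group in set(matrix.sample_types.values()):
        out.setdefault(group, set())
    return out
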