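"""Gene models with exon/CDS structure, plus BED12 I/O.

Coordinates are 0-based, half-open internally; BED12 files follow the BED
convention (which is the same). Splice-site flanks are the two intronic
bases on either side of each internal exon boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

BED12_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "item_rgb", "block_count",
    "block_sizes", "block_starts",
]


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene: exon blocks plus a CDS (thick) span."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_starts: tuple[int, ...]  # absolute, sorted ascending
    exon_ends: tuple[int, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError("exon_starts and exon_ends length mismatch")
        if not (self.start <= self.cds_start <= self.cds_end <= self.end):
            raise ValueError("CDS span must lie within the gene span")

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exonic intervals clipped to the CDS span, genomic order."""
        out = []
        for s, e in self.exons():
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    def contains(self, pos: int) -> bool:
        """0-based position within the transcribed span."""
        return self.start <= pos < self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons())

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_intervals())

    def splice_site_positions(self) -> set[int]:
        """The 2 intronic bases flanking each internal exon boundary."""
        sites: set[int] = set()
        for i, (s, e) in enumerate(self.exons()):
            if i > 0:  # acceptor side: 2 bases before exon start
                sites.update((s - 2, s - 1))
            if i < self.n_exons - 1:  # donor side: 2 bases after exon end
                sites.update((e, e + 1))
        return sites

    def cds_offset(self, pos: int) -> int:
        """Offset of a genomic position within the spliced CDS, on the
        coding strand (0 = first base of the start codon)."""
        if not self.in_cds(pos):
            raise ValueError(f"position {pos} not in CDS of {self.gene_id}")
        off = 0
        for s, e in self.cds_intervals():
            if s <= pos < e:
                off += pos - s
                break
            off += e - s
        if self.strand == "-":
            off = self.cds_length - 1 - off
        return off

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in coding-strand order."""
        pos = [p for s, e in self.cds_intervals() for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos


def to_bed12(genes: Iterable[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons())
        starts = ",".join(str(s - g.start) for s in g.exon_starts)
        rows.append((g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                     g.cds_start, g.cds_end, "0", g.n_exons, sizes, starts))
    return pd.DataFrame(rows, columns=BED12_COLUMNS)


def from_bed12(df: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for r in df.itertuples(index=False):
        sizes = [int(x) for x in str(r.block_sizes).rstrip(",").split(",")]
        rel = [int(x) for x in str(r.block_starts).rstrip(",").split(",")]
        starts = tuple(int(r.start) + x for x in rel)
        ends = tuple(s + sz for s, sz in zip(starts, sizes))
        genes.append(GeneModel(
            gene_id=str(r.name), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), strand=str(r.strand),
            exon_starts=starts, exon_ends=ends,
            cds_start=int(r.thick_start), cds_end=int(r.thick_end)))
    return genes


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    to_bed12(genes).to_csv(path, sep="\t", header=False, index=False)


def read_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=BED12_COLUMNS,
                     comment="#")
    return from_bed12(df)


def genes_by_id(genes: Sequence[GeneModel]) -> dict[str, GeneModel]:
    return {g.gene_id: g for g in genes}
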