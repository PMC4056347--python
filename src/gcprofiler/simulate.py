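"""Synthetic tumor/normal cohort generator with known ground truth.

Emulates the inputs of a paired WGS/WES cancer-profiling study: windowed
read-depth tracks whose tumor:normal ratio carries purity and copy-number
signal, germline + somatic variant tables with configurable mutation rate
and nonsynonymous/synonymous ratio, and discordant read-pair records
clustered around injected structural-variant breakpoints.

The depth model is the standard admixture mixture: a region with tumor
copy number ``c`` in a sample of purity ``pi`` has expected tumor depth
proportional to ``(pi*c + 2*(1-pi)) / 2`` relative to the diploid normal.
Depth noise is negative-binomial (overdispersed relative to Poisson, as
real short-read depth is); somatic allele fractions are purity-diluted
(``pi/2`` for a heterozygous mutation in a copy-neutral region,
copy-number-adjusted inside CNVs).

All randomness flows from ``SimConfig.seed``; a fixed config reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# stream labels so each generator draws from an independent substream
_STREAM_DEPTH, _STREAM_SEQ, _STREAM_VAR, _STREAM_PAIRS = 1, 2, 3, 4


@dataclass(frozen=True)
class CNVEvent:
    chrom: str
    start: int
    end: int
    tumor_copy_number: int


@dataclass(frozen=True)
class SVEvent:
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    n_support: int
    somatic: bool = True


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated tumor/blood pair."""

    seed: int
    genome_length: int = 30_000_000
    n_chromosomes: int = 2
    window_size: int = 50_000
    purity: float = 0.6
    diploid_depth_mean: float = 30.0
    read_length: int = 100
    depth_dispersion: float = 400.0  # NB size for window read counts; larger = closer to Poisson
    cnv_events: tuple[CNVEvent, ...] = ()
    somatic_rate: float = 2.0        # mutations / Mb of CDS
    germline_rate: float = 1000.0    # variants / Mb genome-wide
    ns_s_ratio: float = 2.5
    indel_fraction: float = 0.1      # fraction of somatic coding events that are indels
    driver_genes: tuple[tuple[str, int], ...] = ()
    sv_events: tuple[SVEvent, ...] = ()
    noise_pair_rate: float = 1.0     # discordant noise pairs / Mb
    sv_scatter: int = 150            # read-end scatter around true breakpoints, bp
    call_quality: float = 60.0
    cnv_bin_size: int = 1000         # bin width for the CNV segmentation track

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0,1], got {self.purity}")
        if self.somatic_rate < 0:
            raise ValueError("somatic_rate must be non-negative")
        if self.germline_rate < 0:
            raise ValueError("germline_rate must be non-negative")
        lengths = self.chrom_lengths()
        for ev in self.cnv_events:
            if ev.chrom not in lengths or not (0 <= ev.start < ev.end <= lengths[ev.chrom]):
                raise ValueError(f"CNV event outside genome: {ev}")
        by_chrom: dict[str, list[CNVEvent]] = {}
        for ev in self.cnv_events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for evs in by_chrom.values():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping CNV events: {a} and {b}")
        for ev in self.sv_events:
            for chrom, pos in ((ev.chrom1, ev.pos1), (ev.chrom2, ev.pos2)):
                if chrom not in lengths or not 0 <= pos < lengths[chrom]:
                    raise ValueError(f"SV breakpoint outside genome: {ev}")

    def chrom_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chromosomes
        lengths = {f"chr{i + 1}": base for i in range(self.n_chromosomes)}
        lengths[f"chr{self.n_chromosomes}"] += self.genome_length % self.n_chromosomes
        return lengths

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class GroundTruth:
    true_purity: float
    somatic_variant_ids: set[str] = field(default_factory=set)
    germline_variant_ids: set[str] = field(default_factory=set)
    true_sv_breakpoints: list[SVEvent] = field(default_factory=list)
    gene_truth: dict[str, int] = field(default_factory=dict)
    cnv_events: tuple[CNVEvent, ...] = ()


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


# ---------------------------------------------------------------------------
# depth profile

def _nb_draws(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    r = float(dispersion)
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def _copy_multiplier(config: SimConfig, chrom: str, start: int,
                     end: int) -> float:
    """Expected tumor depth multiplier for a window, admixture-weighted
    over any CNV overlap (normal diploid = 1.0)."""
    pi = config.purity
    total = end - start
    mult = 0.0
    covered = 0
    for ev in config.cnv_events:
        if ev.chrom != chrom:
            continue
        ov = min(end, ev.end) - max(start, ev.start)
        if ov > 0:
            m = (pi * ev.tumor_copy_number + 2.0 * (1.0 - pi)) / 2.0
            mult += ov * m
            covered += ov
    mult += (total - covered) * 1.0
    return mult / total


def simulate_genome_profile(
        config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Windowed tumor and normal depth tracks plus ground truth.

    Returns two DataFrames (chrom, start, end, depth) on identical
    windows, and the GroundTruth carrying purity and the CNV events.
    """
    rng = config.rng(_STREAM_DEPTH)
    rows = []
    for chrom, length in config.chrom_lengths().items():
        for start in range(0, length, config.window_size):
            end = min(start + config.window_size, length)
            rows.append((chrom, start, end))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    mult = np.array([
        _copy_multiplier(config, r.chrom, r.start, r.end)
        for r in windows.itertuples(index=False)])
    # windows aggregate many reads: draw NB read counts per window and
    # report the implied mean depth (count * read_length / width)
    width = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    reads_per_window = config.diploid_depth_mean * width / config.read_length
    normal = windows.copy()
    normal["depth"] = (_nb_draws(rng, reads_per_window, config.depth_dispersion)
                       * config.read_length / width)
    tumor = windows.copy()
    tumor["depth"] = (_nb_draws(rng, reads_per_window * mult,
                                config.depth_dispersion)
                      * config.read_length / width)
    truth = GroundTruth(true_purity=config.purity, cnv_events=config.cnv_events)
    return tumor, normal, truth


# ---------------------------------------------------------------------------
# genome sequence and gene models

def random_genome(config: SimConfig) -> dict[str, str]:
    """Uniform-random reference sequence per chromosome."""
    rng = config.rng(_STREAM_SEQ)
    out = {}
    for chrom, length in config.chrom_lengths().items():
        idx = rng.integers(0, 4, size=length)
        out[chrom] = BASES[idx].tobytes().decode("ascii")
    return out


def make_gene_models(config: SimConfig, n_genes: int = 100,
                     n_exons: int = 5,
                     exon_length: int | Sequence[int] = 300,
                     intron_length: int = 1000) -> list[GeneModel]:
    """Evenly spaced synthetic genes, alternating strand, whole exonic
    span coding. ``exon_length`` may be a sequence, cycled per gene, to
    produce a spread of CDS lengths. Deterministic in the config (no
    random draws)."""
    lengths = config.chrom_lengths()
    exon_lengths = ([exon_length] if isinstance(exon_length, int)
                    else list(exon_length))
    if any(el % 3 for el in exon_lengths):
        raise ValueError("exon lengths must be codon multiples")
    max_span = n_exons * max(exon_lengths) + (n_exons - 1) * intron_length
    genes: list[GeneModel] = []
    chroms = list(lengths)
    per_chrom = -(-n_genes // len(chroms))  # ceil
    gid = 0
    for chrom in chroms:
        if gid >= n_genes:
            break
        usable = lengths[chrom]
        pitch = usable // per_chrom
        if pitch < max_span + 2000:
            raise ValueError("genome too small for requested gene models")
        for k in range(per_chrom):
            if gid >= n_genes:
                break
            el = exon_lengths[gid % len(exon_lengths)]
            start = k * pitch + 1000
            exon_starts = tuple(start + i * (el + intron_length)
                                for i in range(n_exons))
            exon_ends = tuple(s + el for s in exon_starts)
            genes.append(GeneModel(
                gene_id=f"gene{gid:04d}", chrom=chrom, start=start,
                end=exon_ends[-1], strand="+" if gid % 2 == 0 else "-",
                exon_starts=exon_starts, exon_ends=exon_ends,
                cds_start=start, cds_end=exon_ends[-1]))
            gid += 1
    return genes


# ---------------------------------------------------------------------------
# variant tables

def _draw_coding_snv(rng: np.random.Generator, genome: dict[str, str],
                     genes: Sequence[GeneModel], want_ns: bool,
                     used: set[tuple[str, int]],
                     cds_cache: dict[str, np.ndarray],
                     gene_pool: Sequence[int] | None = None,
                     cds_weights: np.ndarray | None = None,
                     max_tries: int = 500) -> tuple[GeneModel, int, str, str]:
    """Rejection-sample a CDS SNV of the requested (non)synonymous class.

    ``cds_cache`` maps gene_id to its CDS genomic positions in
    coding-strand order, so index i in the array is CDS offset i.
    Without an explicit gene pool, genes are drawn proportionally to
    their CDS length (``cds_weights``: cumulative fractions), so
    mutation intensity is uniform per coding base.
    """
    from .somatic import codon_aa

    pool = list(range(len(genes))) if gene_pool is None else list(gene_pool)
    for _ in range(max_tries):
        if gene_pool is None and cds_weights is not None:
            gene = genes[int(np.searchsorted(cds_weights, rng.random()))]
        else:
            gene = genes[pool[int(rng.integers(len(pool)))]]
        arr = cds_cache[gene.gene_id]
        n_full = len(arr) - len(arr) % 3
        i = int(rng.integers(n_full))
        pos = int(arr[i])
        if (gene.chrom, pos) in used:
            continue
        seq = genome[gene.chrom]
        ref = seq[pos]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        cpos = arr[3 * (i // 3): 3 * (i // 3) + 3]
        if gene.strand == "+":
            codon = seq[cpos[0]] + seq[cpos[1]] + seq[cpos[2]]
            alt_coding = alt
        else:
            codon = (_COMPLEMENT[seq[cpos[0]]] + _COMPLEMENT[seq[cpos[1]]]
                     + _COMPLEMENT[seq[cpos[2]]])
            alt_coding = _COMPLEMENT[alt]
        mut = list(codon)
        mut[i % 3] = alt_coding
        is_ns = codon_aa(codon) != codon_aa("".join(mut))
        if is_ns == want_ns:
            return gene, pos, ref, alt
    raise RuntimeError("could not draw a coding SNV of the requested class")


def simulate_variant_tables(
        config: SimConfig, gene_models: Sequence[GeneModel],
        genome: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired tumor and blood variant/pileup tables.

    Germline variants appear as calls in both tables at allele fraction
    ~0.5. Somatic variants appear as tumor calls with purity-diluted
    allele fraction; the blood table carries reference-supporting pileup
    rows (``called=False``) at those positions. Coding somatic SNVs are
    drawn nonsynonymous vs synonymous at the configured ns/s ratio;
    driver genes receive their configured extra nsSNV count.
    """
    if genome is None:
        genome = random_genome(config)
    rng = config.rng(_STREAM_VAR)
    lengths = config.chrom_lengths()
    chroms = list(lengths)
    truth = GroundTruth(true_purity=config.purity,
                        cnv_events=config.cnv_events)
    used: set[tuple[str, int]] = set()
    tumor_rows, blood_rows = [], []

    def depth(rng):
        return max(1, int(_nb_draws(rng, np.array([config.diploid_depth_mean]),
                                    config.depth_dispersion)[0]))

    def somatic_af(chrom: str, pos: int) -> float:
        pi = config.purity
        c = 2
        for ev in config.cnv_events:
            if ev.chrom == chrom and ev.start <= pos < ev.end:
                c = ev.tumor_copy_number
        denom = pi * c + 2.0 * (1.0 - pi)
        return pi / denom if denom > 0 else 0.0

    # sorted, non-overlapping exon arrays per chromosome for fast lookup
    exon_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        ivals = sorted((s, e) for g in gene_models if g.chrom == chrom
                       for s, e in g.exons())
        exon_arrays[chrom] = (np.array([s for s, _ in ivals], dtype=int),
                              np.array([e for _, e in ivals], dtype=int))

    def detected_by(chrom: str, pos: int) -> frozenset:
        starts, ends = exon_arrays[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return frozenset({"WGS", "WES"})
        return frozenset({"WGS"})

    # --- germline SNVs, genome-wide
    n_germ = rng.poisson(config.germline_rate * config.genome_length / 1e6)
    for _ in range(n_germ):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(lengths[chrom]))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = genome[chrom][pos]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        vid = variant_id(chrom, pos + 1, ref, alt)
        truth.germline_variant_ids.add(vid)
        det = detected_by(chrom, pos)
        for rows in (tumor_rows, blood_rows):
            d = depth(rng)
            rows.append((chrom, pos + 1, ref, alt, "SNV", d,
                         int(rng.binomial(d, 0.5)), config.call_quality,
                         True, det, True))

    # --- somatic coding events at somatic_rate per Mb of CDS
    cds_cache = {g.gene_id: np.asarray(g.cds_genomic_positions(), dtype=int)
                 for g in gene_models}
    cds_bases = sum(g.cds_length for g in gene_models)
    cds_weights = np.cumsum([g.cds_length for g in gene_models]) / cds_bases
    p_ns = config.ns_s_ratio / (1.0 + config.ns_s_ratio)
    n_som = rng.poisson(config.somatic_rate * cds_bases / 1e6)
    events: list[tuple] = []  # (gene, pos, ref, alt, vtype, is_ns)
    for _ in range(n_som):
        if rng.random() < config.indel_fraction:
            gene = gene_models[int(np.searchsorted(cds_weights,
                                                   rng.random()))]
            cds = np.sort(cds_cache[gene.gene_id])
            pos = int(cds[rng.integers(len(cds) - 4)])
            if (gene.chrom, pos) in used:
                continue
            length = int(rng.integers(1, 3))  # 1-2 bp -> frameshift
            seq = genome[gene.chrom]
            if rng.random() < 0.5:
                ref, alt = seq[pos:pos + 1 + length], seq[pos]
                vtype = "DEL"
            else:
                ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, length))
                ref, alt = seq[pos], seq[pos] + ins
                vtype = "INS"
            events.append((gene, pos, ref, alt, vtype, False))
            used.add((gene.chrom, pos))
        else:
            want_ns = bool(rng.random() < p_ns)
            gene, pos, ref, alt = _draw_coding_snv(rng, genome, gene_models,
                                                   want_ns, used, cds_cache,
                                                   cds_weights=cds_weights)
            events.append((gene, pos, ref, alt, "SNV", want_ns))
            used.add((gene.chrom, pos))

    # --- driver injections: extra nsSNVs in designated genes
    gene_index = {g.gene_id: i for i, g in enumerate(gene_models)}
    for gene_id, extra in config.driver_genes:
        for _ in range(extra):
            gene, pos, ref, alt = _draw_coding_snv(
                rng, genome, gene_models, True, used, cds_cache,
                gene_pool=[gene_index[gene_id]])
            events.append((gene, pos, ref, alt, "SNV", True))
            used.add((gene.chrom, pos))

    for gene, pos, ref, alt, vtype, is_ns in events:
        chrom = gene.chrom
        vid = variant_id(chrom, pos + 1, ref, alt)
        truth.somatic_variant_ids.add(vid)
        if is_ns:
            truth.gene_truth[gene.gene_id] = truth.gene_truth.get(gene.gene_id, 0) + 1
        af = somatic_af(chrom, pos)
        d = depth(rng)
        alt_reads = max(1, int(rng.binomial(d, af))) if af > 0 else 0
        tumor_rows.append((chrom, pos + 1, ref, alt, vtype, d, alt_reads,
                           config.call_quality, True,
                           frozenset({"WGS", "WES"}), True))
        d_b = depth(rng)
        blood_rows.append((chrom, pos + 1, ref, alt, vtype, d_b, 0,
                           0.0, True, frozenset(), False))

    cols = ["chrom", "pos", "ref", "alt", "vtype", "depth", "alt_reads",
            "call_quality", "uniquely_mapped", "detected_by", "called"]
    tumor = pd.DataFrame(tumor_rows, columns=cols)
    blood = pd.DataFrame(blood_rows, columns=cols)
    order = ["chrom", "pos"]
    tumor = tumor.sort_values(order, kind="stable").reset_index(drop=True)
    blood = blood.sort_values(order, kind="stable").reset_index(drop=True)
    return tumor, blood, truth


def blood_pileup(blood_table: pd.DataFrame) -> pd.DataFrame:
    """Per-position blood pileup summary (chrom, pos, depth, alt_ratio)."""
    df = blood_table.copy()
    with np.errstate(invalid="ignore"):
        df["alt_ratio"] = np.where(df["depth"] > 0,
                                   df["alt_reads"] / df["depth"], 0.0)
    return df[["chrom", "pos", "depth", "alt_ratio"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# discordant read pairs

_STRANDS_BY_TYPE = {
    "deletion": ("+", "-"),
    "insertion": ("+", "-"),
    "inversion": ("+", "+"),
    "intra_translocation": ("-", "+"),
    "inter_translocation": ("+", "-"),
}


def _emit_pairs(rng: np.random.Generator, ev: SVEvent, scatter: int,
                lengths: dict[str, int]) -> list[tuple]:
    s1, s2 = _STRANDS_BY_TYPE[ev.sv_type]
    rows = []
    for _ in range(ev.n_support):
        p1 = ev.pos1 + (int(rng.integers(-scatter, scatter + 1)) if scatter else 0)
        p2 = ev.pos2 + (int(rng.integers(-scatter, scatter + 1)) if scatter else 0)
        p1 = min(max(p1, 0), lengths[ev.chrom1] - 1)
        p2 = min(max(p2, 0), lengths[ev.chrom2] - 1)
        c1, c2, q1, q2, t1, t2 = ev.chrom1, ev.chrom2, p1, p2, s1, s2
        if (c1, q1) > (c2, q2):  # normalize mate order
            c1, c2, q1, q2, t1, t2 = c2, c1, q2, q1, t2, t1
        rows.append((c1, q1, t1, c2, q2, t2, True))
    return rows


def simulate_read_pairs(
        config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discordant read-pair tables for tumor and blood.

    Somatic SV events emit supporting pairs in the tumor only; germline
    events emit (independently scattered) pairs in both samples. Noise
    pairs are uniform over the genome in both samples.
    """
    rng = config.rng(_STREAM_PAIRS)
    lengths = config.chrom_lengths()
    chroms = list(lengths)
    tumor_rows, blood_rows = [], []
    for ev in config.sv_events:
        tumor_rows.extend(_emit_pairs(rng, ev, config.sv_scatter, lengths))
        if not ev.somatic:
            blood_rows.extend(_emit_pairs(rng, ev, config.sv_scatter, lengths))

    def noise(rows):
        n = rng.poisson(config.noise_pair_rate * config.genome_length / 1e6)
        for _ in range(n):
            c1 = chroms[int(rng.integers(len(chroms)))]
            c2 = chroms[int(rng.integers(len(chroms)))]
            p1 = int(rng.integers(lengths[c1]))
            p2 = int(rng.integers(lengths[c2]))
            s1 = "+-"[int(rng.integers(2))]
            s2 = "+-"[int(rng.integers(2))]
            if (c1, p1) > (c2, p2):
                c1, c2, p1, p2, s1, s2 = c2, c1, p2, p1, s2, s1
            rows.append((c1, p1, s1, c2, p2, s2, True))

    noise(tumor_rows)
    noise(blood_rows)
    cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
            "uniquely_mapped"]
    tumor = pd.DataFrame(tumor_rows, columns=cols)
    blood = pd.DataFrame(blood_rows, columns=cols)
    key = ["chrom1", "pos1", "chrom2", "pos2"]
    tumor = tumor.sort_values(key, kind="stable").reset_index(drop=True)
    blood = blood.sort_values(key, kind="stable").reset_index(drop=True)
    return tumor, blood
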