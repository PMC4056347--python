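"""End-to-end orchestration: per-sample stage runs and cohort reports.

A sample is a tumor/blood pair. ``run_sample`` executes purity ->
somatic filtering/annotation -> SV clustering -> CNV segmentation for
one pair; ``run_cohort`` aggregates samples, scores drivers across the
cohort, builds the integrated alteration matrix and the DGC/IGC
comparisons. All stage parameters are defaults from the profiling
protocol and can be overridden; stage outputs are plain DataFrames /
dataclasses so every reported number is traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import drivers as drv
from . import purity as pur
from . import somatic as som
from . import svs as sv_mod
from .genes import GeneModel, write_bed12
from .simulate import (SimConfig, blood_pileup, random_genome,
                       simulate_genome_profile, simulate_read_pairs,
                       simulate_variant_tables)

DEFAULT_READ_LENGTH = 100


@dataclass
class SampleInputs:
    sample: str
    group: str  # DGC | IGC
    tumor_windows: pd.DataFrame
    normal_windows: pd.DataFrame
    tumor_calls: pd.DataFrame
    blood_calls: pd.DataFrame
    tumor_pairs: pd.DataFrame
    blood_pairs: pd.DataFrame
    truth: object | None = None
    genome: dict[str, str] | None = None
    bins: pd.DataFrame | None = None  # chrom,start,end,tumor_count,normal_count


@dataclass
class SampleResult:
    sample: str
    group: str
    purity: pur.PurityEstimate
    somatic_variants: pd.DataFrame
    cascade_audit: som.CascadeAudit
    mutation_rate: float
    spectrum: pd.Series
    somatic_svs: list
    impaired_genes: set[str]
    segments: list
    gene_cnv: pd.DataFrame


@dataclass
class CohortReport:
    per_sample: pd.DataFrame
    driver_table: pd.DataFrame
    sv_summary: pd.DataFrame
    matrix: cnv_mod.AlterationMatrix
    comparison: cnv_mod.CohortComparison | None
    warnings: list[str] = field(default_factory=list)


def simulate_sample(config: SimConfig, genes: Sequence[GeneModel],
                    sample: str, group: str,
                    genome: dict[str, str] | None = None) -> SampleInputs:
    """All pipeline inputs for one simulated tumor/blood pair."""
    if genome is None:
        genome = random_genome(config)
    tumor_w, normal_w, truth = simulate_genome_profile(config)
    tumor_c, blood_c, vtruth = simulate_variant_tables(config, genes, genome)
    truth.somatic_variant_ids = vtruth.somatic_variant_ids
    truth.germline_variant_ids = vtruth.germline_variant_ids
    truth.gene_truth = vtruth.gene_truth
    truth.true_sv_breakpoints = list(config.sv_events)
    tumor_p, blood_p = simulate_read_pairs(config)
    # fine-grained count track for CNV segmentation (protocol bin size)
    from dataclasses import replace

    bin_cfg = replace(config, window_size=config.cnv_bin_size)
    tumor_b, normal_b, _ = simulate_genome_profile(bin_cfg)
    bins = bins_from_windows(tumor_b, normal_b, config.read_length)
    return SampleInputs(sample=sample, group=group,
                        tumor_windows=tumor_w, normal_windows=normal_w,
                        tumor_calls=tumor_c, blood_calls=blood_c,
                        tumor_pairs=tumor_p, blood_pairs=blood_p,
                        truth=truth, genome=genome, bins=bins)


def bins_from_windows(tumor_windows: pd.DataFrame,
                      normal_windows: pd.DataFrame,
                      read_length: int = DEFAULT_READ_LENGTH) -> pd.DataFrame:
    """Binned read counts from mean-depth windows (count ~ depth *
    width / read length)."""
    width = (tumor_windows["end"] - tumor_windows["start"])
    return pd.DataFrame({
        "chrom": tumor_windows["chrom"],
        "start": tumor_windows["start"],
        "end": tumor_windows["end"],
        "tumor_count": (tumor_windows["depth"] * width / read_length).round(),
        "normal_count": (normal_windows["depth"] * width / read_length).round(),
    })


def _deletion_regions(svs_list: Sequence[sv_mod.SVS]) -> pd.DataFrame:
    rows = [{"chrom": s.chrom1, "start": s.bp1_start, "end": s.bp2_end}
            for s in svs_list
            if s.sv_type == "deletion" and s.chrom1 == s.chrom2]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def run_sample(inputs: SampleInputs, genes: Sequence[GeneModel],
               genome: Mapping[str, str] | None = None,
               dup_regions: pd.DataFrame | None = None,
               known_variant_sets: Sequence[set] = (),
               library_stats: sv_mod.LibraryStats = sv_mod.LibraryStats(),
               cnv_lambda: float = cnv_mod.DEFAULT_LAMBDA) -> SampleResult:
    """Run all per-sample stages for one tumor/blood pair."""
    for attr in ("tumor_windows", "normal_windows", "tumor_calls",
                 "blood_calls", "tumor_pairs", "blood_pairs"):
        if getattr(inputs, attr) is None:
            stage = {"tumor_windows": "purity", "normal_windows": "purity",
                     "tumor_calls": "somatic_variants",
                     "blood_calls": "somatic_variants",
                     "tumor_pairs": "sv_fusion",
                     "blood_pairs": "sv_fusion"}[attr]
            raise ValueError(f"stage {stage}: missing input {attr} for "
                             f"sample {inputs.sample}")

    # SV stage first: somatic deletions can anchor low-purity estimation
    tumor_svs = sv_mod.cluster_svs(inputs.tumor_pairs, library_stats)
    blood_svs = sv_mod.cluster_svs(inputs.blood_pairs, library_stats)
    som_svs = sv_mod.somatic_svs(tumor_svs, blood_svs)
    impaired = sv_mod.gene_breakage(som_svs, genes, exon_filter=False)

    est = pur.estimate_purity(
        inputs.tumor_windows, inputs.normal_windows,
        somatic_deletions=_deletion_regions(som_svs),
        blood_deletions=_deletion_regions(blood_svs))

    pileup = blood_pileup(inputs.blood_calls)
    survivors, audit = som.filter_somatic(
        inputs.tumor_calls, inputs.blood_calls, pileup,
        dup_regions=dup_regions, known_variant_sets=known_variant_sets)
    if genome is None:
        genome = inputs.genome
    annotated = som.annotate_table(survivors, genes,
                                   dict(genome) if genome else None)
    cds_mask = pd.DataFrame(
        [{"chrom": g.chrom, "start": s, "end": e}
         for g in genes for s, e in g.cds_intervals()])
    rate = som.mutation_rate(annotated, cds_mask)
    spectrum = som.mutation_spectrum(annotated)

    bins = (inputs.bins if inputs.bins is not None
            else bins_from_windows(inputs.tumor_windows,
                                   inputs.normal_windows))
    segments = cnv_mod.classify_segments(
        cnv_mod.segment_depth_bins(bins, lam=cnv_lambda))
    gene_cnv = cnv_mod.gene_copy_status(segments, genes)

    return SampleResult(
        sample=inputs.sample, group=inputs.group, purity=est,
        somatic_variants=annotated, cascade_audit=audit,
        mutation_rate=rate, spectrum=spectrum, somatic_svs=som_svs,
        impaired_genes=impaired, segments=segments, gene_cnv=gene_cnv)


def run_cohort(inputs: Sequence[SampleInputs], genes: Sequence[GeneModel],
               genome: Mapping[str, str] | None = None,
               **sample_kwargs) -> CohortReport:
    """Per-sample runs plus cohort-level aggregation."""
    results = [run_sample(si, genes, genome, **sample_kwargs)
               for si in inputs]
    warnings: list[str] = []

    per_sample = pd.DataFrame([{
        "sample": r.sample, "group": r.group,
        "purity": r.purity.P if r.purity.P is not None else np.nan,
        "purity_method": r.purity.method,
        "n_somatic": len(r.somatic_variants),
        "mutation_rate_per_mb": r.mutation_rate,
        "n_somatic_svs": len(r.somatic_svs),
        "n_impaired_genes": len(r.impaired_genes),
    } for r in results])

    # cohort driver scoring on pooled annotated somatic variants
    pooled = pd.concat(
        [r.somatic_variants.assign(sample=r.sample) for r in results],
        ignore_index=True)
    coverage = pd.DataFrame([{"gene_id": g.gene_id,
                              "covered_bases": g.cds_length}
                             for g in genes])
    driver_table = drv.score_cohort(pooled, coverage)

    sample_types = {r.sample: r.group for r in results}
    sv_summary = sv_mod.summarize_sv_counts(
        {r.sample: r.somatic_svs for r in results}, sample_types)

    gene_cnv_long = pd.concat(
        [r.gene_cnv.assign(sample=r.sample) for r in results],
        ignore_index=True)
    impaired_long = pd.DataFrame(
        [{"sample": r.sample, "gene_id": g}
         for r in results for g in sorted(r.impaired_genes)],
        columns=["sample", "gene_id"])
    matrix = cnv_mod.build_alteration_matrix(
        pooled, gene_cnv_long, impaired_long, sample_types)

    comparison = None
    groups = sorted(set(sample_types.values()))
    if len(groups) == 2:
        sets = cnv_mod.mutated_gene_sets(matrix, qualifying=("SNV",))
        comparison = cnv_mod.cohort_compare(sets[groups[0]], sets[groups[1]])
    else:
        warnings.append("single-type cohort: DGC/IGC comparison skipped")

    report = CohortReport(per_sample=per_sample, driver_table=driver_table,
                          sv_summary=sv_summary, matrix=matrix,
                          comparison=comparison, warnings=warnings)
    _consistency_pass(report, results)
    return report


def _consistency_pass(report: CohortReport,
                      results: Sequence[SampleResult]) -> None:
    """Every CohortReport number equals the corresponding stage output."""
    for r in results:
        row = report.per_sample.set_index("sample").loc[r.sample]
        assert row["n_somatic"] == len(r.somatic_variants)
        assert row["n_somatic_svs"] == len(r.somatic_svs)
        if r.purity.P is not None:
            assert row["purity"] == r.purity.P


def simulate_cohort(base_seed: int, n_dgc: int, n_igc: int,
                    genes: Sequence[GeneModel], base_config: SimConfig,
                    genome: dict[str, str] | None = None,
                    ) -> list[SampleInputs]:
    """A DGC/IGC cohort of independent samples derived from one seed."""
    from dataclasses import replace

    out = []
    for i in range(n_dgc + n_igc):
        group = "DGC" if i < n_dgc else "IGC"
        name = (f"D-{i + 1:02d}" if group == "DGC"
                else f"I-{i - n_dgc + 1:02d}")
        cfg = replace(base_config, seed=base_seed + i)
        out.append(simulate_sample(cfg, genes, name, group, genome))
    return out


def write_sample_inputs(inputs: SampleInputs, outdir: Path,
                        contigs: Mapping[str, int]) -> dict[str, Path]:
    """Serialize one sample's inputs in their interchange formats."""
    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = inputs.sample
    paths = {
        "tumor_bedgraph": outdir / f"{s}.tumor.bedgraph",
        "normal_bedgraph": outdir / f"{s}.normal.bedgraph",
        "tumor_vcf": outdir / f"{s}.tumor.vcf",
        "blood_vcf": outdir / f"{s}.blood.vcf",
        "pileup": outdir / f"{s}.blood.pileup.tsv",
        "tumor_bedpe": outdir / f"{s}.tumor.bedpe",
        "blood_bedpe": outdir / f"{s}.blood.bedpe",
    }
    gio.write_bedgraph(inputs.tumor_windows, paths["tumor_bedgraph"],
                       value_col="depth")
    gio.write_bedgraph(inputs.normal_windows, paths["normal_bedgraph"],
                       value_col="depth")
    gio.write_vcf(inputs.tumor_calls, paths["tumor_vcf"], dict(contigs),
                  sample=f"{s}_T")
    blood_called = inputs.blood_calls
    if "called" in blood_called.columns:
        blood_called = blood_called[blood_called["called"]]
    gio.write_vcf(blood_called, paths["blood_vcf"], dict(contigs),
                  sample=f"{s}_B")
    gio.write_pileup(blood_pileup(inputs.blood_calls), paths["pileup"])
    gio.write_bedpe(inputs.tumor_pairs, paths["tumor_bedpe"])
    gio.write_bedpe(inputs.blood_pairs, paths["blood_bedpe"])
    return paths
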