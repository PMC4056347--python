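"""Readers/writers for the tabular genomics formats the pipeline consumes.

Depth tracks are bedGraph, region masks are BED3, discordant read pairs are
BEDPE, variant tables are VCF 4.2 (via pysam). All tables round-trip
through pandas DataFrames with the column names used across the package.
"""

from __future__ import annotations

import pandas as pd
import pysam

BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "strand1", "strand2"]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "depth",
                   "alt_reads", "call_quality", "uniquely_mapped",
                   "detected_by"]


def read_bedgraph(path, value_name: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", value_name],
                     comment="#", dtype={0: str})
    return df


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "value") -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed3(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                       names=["chrom", "start", "end"], comment="#",
                       dtype={0: str})


def write_bed3(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                         index=False)


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLUMNS,
                     comment="#", dtype={0: str, 3: str})
    df["pos1"] = df["start1"].astype(int)
    df["pos2"] = df["start2"].astype(int)
    df["uniquely_mapped"] = df["score"].astype(int) > 0
    return df


def write_bedpe(pairs: pd.DataFrame, path) -> None:
    """Pairs carry chrom1/pos1/strand1, chrom2/pos2/strand2,
    uniquely_mapped; score column encodes the unique-mapping flag."""
    out = pd.DataFrame({
        "chrom1": pairs["chrom1"], "start1": pairs["pos1"],
        "end1": pairs["pos1"] + 1,
        "chrom2": pairs["chrom2"], "start2": pairs["pos2"],
        "end2": pairs["pos2"] + 1,
        "name": [f"pair{i}" for i in range(len(pairs))],
        "score": pairs["uniquely_mapped"].astype(int),
        "strand1": pairs["strand1"], "strand2": pairs["strand2"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def _vcf_header(contigs: dict[str, int], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("VT", 1, "String", "Variant type (SNV/INS/DEL)")
    header.info.add("UM", 0, "Flag", "All supporting reads uniquely mapped")
    header.info.add("DET", ".", "String", "Detection platforms (WGS/WES)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample)
    return header


def write_vcf(variants: pd.DataFrame, path, contigs: dict[str, int],
              sample: str = "SAMPLE") -> None:
    """Write a variant table (VARIANT_COLUMNS; pos is 1-based) as VCF 4.2."""
    header = _vcf_header(contigs, sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in variants.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = vcf.new_record(
                contig=r.chrom, start=int(r.pos) - 1,
                alleles=(r.ref, r.alt), qual=float(r.call_quality))
            rec.info["VT"] = r.vtype
            if bool(r.uniquely_mapped):
                rec.info["UM"] = True
            det = sorted(r.detected_by) if r.detected_by else []
            if det:
                rec.info["DET"] = tuple(det)
            rec.samples[sample]["DP"] = int(r.depth)
            rec.samples[sample]["AD"] = (int(r.depth) - int(r.alt_reads),
                                         int(r.alt_reads))
            vcf.write(rec)


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            ad = rec.samples[sample].get("AD") or (0, 0)
            det = rec.info.get("DET")
            rows.append((
                rec.contig, rec.pos, rec.ref, rec.alts[0],
                rec.info.get("VT", "SNV"),
                rec.samples[sample].get("DP") or 0,
                int(ad[1]),
                float(rec.qual) if rec.qual is not None else 0.0,
                bool(rec.info.get("UM", False)),
                frozenset(det) if det else frozenset(),
            ))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_pileup(path) -> pd.DataFrame:
    """TSV pileup summary: chrom, pos (1-based), depth, alt_ratio."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_pileup(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "depth", "alt_ratio"]].to_csv(path, sep="\t",
                                                      index=False)
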