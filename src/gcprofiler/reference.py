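"""Bundled reference tables.

``cdh1_alterations.tsv`` is the published per-sample CDH1 alteration
table for an 18-patient gastric-cancer cohort (14 diffuse-type, 4
intestinal-type): SNVs, a frameshift insertion, gene copy losses and SV
breakpoints. It serves as a worked example for the alteration-matrix and
mutual-exclusivity operations. Samples without any CDH1 alteration are
listed with category 'none' so the cohort denominators are explicit.

The published cohort-level SV summary (mean somatic SV counts per sample
pair, by class) is provided for the count-integration helpers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cnv import AlterationMatrix

# mean somatic SV counts per sample pair, by class and cohort
SV_CLASS_MEANS = {
    "DGC": {"insertion": 211, "deletion": 264, "inversion": 27,
            "intra_translocation": 44, "inter_translocation": 6},
    "IGC": {"insertion": 285, "deletion": 283, "inversion": 34,
            "intra_translocation": 38, "inter_translocation": 24},
}

# cohort-wide mutated-gene counts (genes hit by somatic nsSNVs)
MUTATED_GENE_COUNTS = {"DGC": 581, "IGC": 288, "common": 22}


def load_cdh1_table() -> pd.DataFrame:
    with resources.files("gcprofiler.data").joinpath(
            "cdh1_alterations.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def cdh1_alteration_matrix() -> AlterationMatrix:
    """The CDH1 table parsed into an AlterationMatrix over 18 samples."""
    df = load_cdh1_table()
    sample_types = dict(zip(df["sample"], df["group"]))
    entries = (df[df["category"] != "none"]
               [["gene", "sample", "category"]].reset_index(drop=True))
    return AlterationMatrix(entries, sample_types)
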