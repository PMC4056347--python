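"""Poisson driver-gene scoring.

A gene's expected nonsynonymous mutation count under the background model
is derived from the cohort-wide nonsynonymous/synonymous ratio and the
observed synonymous count, distributed over each gene's efficiently
covered bases. The observed nsSNV count is compared with the expectation
under a Poisson upper-tail test; the driver score is -log10 of the
Benjamini-Hochberg-adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class Background:
    ns_s_ratio: float
    ns_rate_per_base: float
    n_ns: int
    n_s: int
    covered_bases: int


def background_rates(n_ns: int, n_s: int, total_covered_bases: int,
                     ) -> Background:
    """Cohort background from observed ns and s counts over covered bases.

    ns_s_ratio = ns / s; the expected-ns rate per covered base is
    ns_s_ratio * (s / covered bases) = ns / covered bases.
    """
    if n_s <= 0:
        raise ValueError(
            "zero synonymous SNVs cohort-wide; supply a pseudocount or a "
            "larger cohort to estimate the background")
    if total_covered_bases <= 0:
        raise ValueError("total covered bases must be positive")
    ratio = n_ns / n_s
    rate = ratio * (n_s / total_covered_bases)
    return Background(ns_s_ratio=ratio, ns_rate_per_base=rate,
                      n_ns=n_ns, n_s=n_s,
                      covered_bases=total_covered_bases)


def expected_nssnv(covered_bases: int, background: Background,
                   ns_site_fraction: float | None = None) -> float:
    """Expected nsSNV count for one gene; optional per-gene weighting by
    its fraction of nonsynonymous opportunity (identity when absent)."""
    if covered_bases < 0:
        raise ValueError("covered_bases must be non-negative")
    exp = background.ns_rate_per_base * covered_bases
    if ns_site_fraction is not None:
        if not 0.0 <= ns_site_fraction <= 1.0:
            raise ValueError("ns_site_fraction must be in [0,1]")
        exp *= ns_site_fraction
    return exp


def poisson_pvalue(obs: int, exp: float) -> float:
    """Upper-tail P(X >= obs) for X ~ Poisson(exp); P(obs=0) = 1."""
    if exp <= 0:
        raise ValueError(f"expectation must be positive, got {exp}")
    if obs < 0:
        raise ValueError("observed count must be non-negative")
    return float(poisson.sf(obs - 1, exp))


def score_and_rank(gene_table: pd.DataFrame,
                   n_tested: int | None = None) -> pd.DataFrame:
    """BH-adjust p-values, score = -log10(adj p), and rank.

    ``gene_table`` needs columns gene_id, obs_ns, exp_ns, p_value (and
    optionally n_samples_mutated). Sorting is by raw p ascending, ties by
    obs_ns descending then gene_id. Genes with obs_ns = 0 stay in the
    table (p = 1) so the multiplicity family is well defined.
    """
    df = gene_table.copy()
    m = n_tested if n_tested is not None else len(df)
    if m < len(df):
        raise ValueError("n_tested smaller than the number of genes")
    pvals = df["p_value"].values.astype(float)
    if len(df):
        # BH over the declared family size; pad with p=1 placeholders
        padded = np.concatenate([pvals, np.ones(m - len(df))])
        _, adj, _, _ = multipletests(padded, method="fdr_bh")
        df["adj_p"] = np.minimum(adj[:len(df)], 1.0)
    else:
        df["adj_p"] = pd.Series(dtype=float)
    with np.errstate(divide="ignore"):
        df["score"] = -np.log10(df["adj_p"])
    df = df.sort_values(
        ["p_value", "obs_ns", "gene_id"],
        ascending=[True, False, True], kind="stable").reset_index(drop=True)
    return df


def score_cohort(somatic_annotated: pd.DataFrame,
                 coverage: pd.DataFrame,
                 include_indels: bool = False) -> pd.DataFrame:
    """Full scoring pass over a cohort.

    ``somatic_annotated``: one row per surviving somatic variant with
    sample, gene_id, consequence, vtype columns. ``coverage``: gene_id,
    covered_bases (and optional ns_site_fraction). By default only
    nsSNVs (incl. nonsense) enter the observed count; splice-site SNVs
    and indels are tabulated in their own columns, and can be folded into
    the count with ``include_indels``.
    """
    snvs = somatic_annotated[somatic_annotated["vtype"] == "SNV"]
    ns_mask = snvs["consequence"].isin(["nonsynonymous", "nonsense"])
    n_ns = int(ns_mask.sum())
    n_s = int((snvs["consequence"] == "synonymous").sum())
    cov = coverage.set_index("gene_id")
    excluded = cov[cov["covered_bases"] <= 0]
    cov = cov[cov["covered_bases"] > 0]
    bg = background_rates(n_ns, n_s, int(cov["covered_bases"].sum()))

    rows = []
    by_gene = somatic_annotated.groupby("gene_id", dropna=True)
    for gene_id, cdata in cov.iterrows():
        sub = (by_gene.get_group(gene_id)
               if gene_id in by_gene.groups else somatic_annotated.iloc[:0])
        gsnv = sub[sub["vtype"] == "SNV"]
        obs_ns = int(gsnv["consequence"].isin(
            ["nonsynonymous", "nonsense"]).sum())
        n_splice = int((gsnv["consequence"] == "splice_site").sum())
        n_indel = int(sub["vtype"].isin(["INS", "DEL"]).sum())
        if include_indels:
            obs_ns += n_indel
        frac = cdata.get("ns_site_fraction", None)
        if frac is not None and pd.isna(frac):
            frac = None
        exp = expected_nssnv(int(cdata["covered_bases"]), bg, frac)
        p = poisson_pvalue(obs_ns, exp) if exp > 0 else 1.0
        n_samples = sub["sample"].nunique() if "sample" in sub.columns else 0
        rows.append((gene_id, n_samples, obs_ns, n_splice, n_indel, exp, p))
    table = pd.DataFrame(rows, columns=[
        "gene_id", "n_samples_mutated", "obs_ns", "n_splice_snvs",
        "n_indels", "exp_ns", "p_value"])
    ranked = score_and_rank(table)
    ranked.attrs["background"] = bg
    ranked.attrs["excluded_genes"] = list(excluded.index)
    return ranked
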