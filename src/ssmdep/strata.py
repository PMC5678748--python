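"""Covariate stratification: exon-score quartiles, gene classes, sample
splits, and routing strata through the flank/core comparison.

The stratified comparisons address the mutational-heterogeneity
alternative: if the flank deficit were driven by nucleosome occupancy,
replication timing or repair status, it would concentrate in the
corresponding strata; the paired battery is therefore re-run per
stratum on otherwise identical settings.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .depletion import flank_core_study

logger = logging.getLogger(__name__)


def quartile_strata(exon_scores: pd.Series, upper_q: float = 0.25, lower_q: float = 0.25):
    """Split exon keys into (high, low) sets by score quantiles.

    ``high`` holds exons with score >= the (1 - upper_q) quantile,
    ``low`` those with score <= the lower_q quantile; degenerate
    (all-identical) scores raise.
    """
    scores = exon_scores.astype(float)
    if len(scores) < 4:
        raise ValueError("need at least 4 scored exons")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; quantile strata undefined")
    hi_thr = np.quantile(scores.to_numpy(), 1 - upper_q)
    lo_thr = np.quantile(scores.to_numpy(), lower_q)
    high = set(scores.index[scores >= hi_thr])
    low = set(scores.index[scores <= lo_thr])
    overlap = high & low
    if overlap:
        # can only happen for very coarse quantiles; keep the sets disjoint
        high -= overlap
        low -= overlap
        logger.warning("dropped %d exons on both quantile boundaries", len(overlap))
    return high, low


def partition_genes(gene_table: pd.DataFrame, all_gene_ids) -> dict:
    """gene id sets per cancer class: oncogene / tumour_suppressor / non_cancer.

    Genes annotated as both oncogene and tumour suppressor are excluded
    (logged); genes absent from the table are non_cancer.
    """
    classes = {"oncogene": set(), "tumour_suppressor": set(), "non_cancer": set()}
    seen = {}
    dual = set()
    for gene, label in zip(gene_table["gene_id"], gene_table["cancer_class"]):
        if label not in ("oncogene", "tumour_suppressor"):
            continue
        if gene in seen and seen[gene] != label:
            dual.add(gene)
        seen[gene] = label
    if dual:
        logger.warning("excluded %d dual-annotated genes from the cancer-class split", len(dual))
    for gene in all_gene_ids:
        if gene in dual:
            continue
        classes[seen.get(gene, "non_cancer")].add(gene)
    return classes


def split_samples(sample_table: pd.DataFrame, key: str = "msi_status") -> dict:
    """Disjoint sample-id sets per category of ``key`` ('unknown' kept separate)."""
    if key not in sample_table.columns:
        raise ValueError(f"column {key!r} not in sample table")
    out = {}
    for sample, value in zip(sample_table["sample_id"], sample_table[key]):
        label = str(value) if pd.notna(value) else "unknown"
        out.setdefault(label, set()).add(sample)
    return out


def run_stratified_comparison(
    strata: dict,
    muts: pd.DataFrame,
    genome,
    all_exons,
    samples,
    **study_kwargs,
) -> pd.DataFrame:
    """Run the flank/core battery per stratum and tabulate side by side.

    ``strata`` maps stratum name to a dict with optional keys
    ``exons`` (an exon subset; default: all) and ``samples`` (a sample
    subset; default: all). Empty strata are skipped with a log entry.
    """
    rows = []
    for name, spec in strata.items():
        exons = spec.get("exons", all_exons)
        stratum_samples = sorted(spec.get("samples", samples))
        if not exons or not stratum_samples:
            logger.warning("stratum %s empty; skipped", name)
            continue
        sub = muts[muts["sample_id"].isin(stratum_samples)]
        result = flank_core_study(
            sub, exons, genome, {name: stratum_samples}, **study_kwargs
        )
        c = result.cohorts[0]
        rows.append(
            {
                "stratum": name,
                "n_exons": len(exons),
                "n_tumours": c.n_tumours,
                "flank_rate": c.mean_rate["flank"],
                "core_rate": c.mean_rate["core"],
                "wilcoxon_p": c.wilcoxon_p,
                "depletion": c.depletion,
            }
        )
    return pd.DataFrame(rows)


def exons_for_genes(exons, gene_ids) -> list:
    return [e for e in exons if e.parent.gene_id in gene_ids]


def exons_for_keys(exons, keys) -> list:
    keys = set(keys)
    return [e for e in exons if e.key in keys]
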