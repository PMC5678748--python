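"""Cohort-level flank-vs-core and ESE-vs-non-ESE depletion analyses.

These functions tie the interval, counting and statistics layers into
the study design: per cohort, synonymous calls are counted in the two
region groups, per-tumour paired rates feed a Wilcoxon signed-rank
test, pooled densities get percentile-bootstrap CIs, and cohorts are
combined by Fisher's method with a Cohen's d over cohort-level mean
rates. The headline estimand is the depletion fraction
``1 - rate(flank) / rate(core)`` (resp. ESE vs non-ESE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import fetch, revcomp
from .counting import (
    attach_bootstrap_ci,
    cpg_mask_for_region_set,
    depletion_fraction,
    per_tumour_density_table,
    ssm_density,
)
from .hexamers import build_non_ese_set, resolve_overlaps, scan_hexamer_regions
from .intervals import (
    GenomicInterval,
    RegionSet,
    build_flank_core_region_set,
    exon_relative_to_genome,
)
from .stats import (
    CohortResult,
    CombinedResult,
    binomial_sign_test,
    cohens_d,
    fishers_combined,
    wilcoxon_signed_rank,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Per-cohort results plus the Fisher's-method combination."""

    cohorts: list
    combined: CombinedResult
    per_tumour: pd.DataFrame
    region_set: RegionSet = None
    groups: tuple = ("flank", "core")

    def cohort_table(self) -> pd.DataFrame:
        g1, g2 = self.groups
        rows = []
        for c in self.cohorts:
            rows.append(
                {
                    "cohort": c.cohort,
                    "n_tumours": c.n_tumours,
                    f"{g1}_rate": c.mean_rate.get(g1),
                    f"{g2}_rate": c.mean_rate.get(g2),
                    "wilcoxon_p": c.wilcoxon_p,
                    "depletion": c.depletion,
                    "flank5_rate": c.flank5_rate,
                    "flank3_rate": c.flank3_rate,
                    "sign_test_p": c.sign_test_p,
                }
            )
        return pd.DataFrame(rows)


def _filter_consequence(muts: pd.DataFrame, consequence: str) -> pd.DataFrame:
    if consequence == "all":
        return muts
    return muts[muts["consequence"] == consequence]


def _group_per_tumour(table: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Aggregate per-tumour role rows into role groups (counts and bp sum)."""
    role_to_group = {role: g for g, roles in groups.items() for role in roles}
    t = table.copy()
    t["group"] = t["role"].map(role_to_group)
    t = t.dropna(subset=["group"])
    agg = (
        t.groupby(["sample_id", "group"], as_index=False)[["count", "effective_bp"]]
        .sum()
    )
    agg["rate"] = agg["count"] / agg["effective_bp"]
    return agg


def _cohort_result(
    name, muts, region_set, mask, samples, groups, B, confidence, seed
) -> CohortResult:
    table = per_tumour_density_table(muts, region_set, mask, samples=samples)
    agg = _group_per_tumour(table, groups)
    wide = agg.pivot(index="sample_id", columns="group", values="rate")
    g1, g2 = list(groups)
    n = len(samples)
    res = CohortResult(cohort=name, n_tumours=n)
    pooled = (
        agg.groupby("group")[["count"]].sum().join(
            agg.groupby("group")["effective_bp"].first()
        )
    )
    for g in (g1, g2):
        est = ssm_density(int(pooled.loc[g, "count"]), int(pooled.loc[g, "effective_bp"]), n)
        est = attach_bootstrap_ci(est, wide[g].to_numpy(), B=B, confidence=confidence, seed=seed)
        res.density[g] = est
        res.mean_rate[g] = est.rate
    res.wilcoxon_p = wilcoxon_signed_rank(wide[g1].to_numpy(), wide[g2].to_numpy())
    res.depletion = depletion_fraction(res.mean_rate[g1], res.mean_rate[g2])
    # 5' vs 3' split where flanks exist
    if {"flank5", "flank3"} <= set(table["role"]):
        t5 = table[table["role"] == "flank5"].set_index("sample_id")
        t3 = table[table["role"] == "flank3"].set_index("sample_id")
        res.flank5_rate = t5["count"].sum() / (t5["effective_bp"].iloc[0] * n)
        res.flank3_rate = t3["count"].sum() / (t3["effective_bp"].iloc[0] * n)
        informative = (t5["rate"] != t3["rate"])
        res.n_informative_53 = int(informative.sum())
        res.n_flank5_lower = int((t5["rate"][informative] < t3["rate"][informative]).sum())
        if res.n_informative_53:
            res.sign_test_p = binomial_sign_test(
                res.n_flank5_lower, res.n_informative_53, sided="two"
            )
    res._per_tumour = agg  # noqa: SLF001 - internal carry for study assembly
    return res


def _combine(cohorts, g1, g2) -> CombinedResult:
    fisher = fishers_combined([c.wilcoxon_p for c in cohorts])
    if len(cohorts) >= 2:
        d, lo, hi = cohens_d(
            [c.mean_rate[g2] for c in cohorts], [c.mean_rate[g1] for c in cohorts]
        )
        fisher.cohens_d, fisher.d_ci = d, (lo, hi)
    total = {g: (0, 0) for g in (g1, g2)}
    n_total = 0
    for c in cohorts:
        n_total += c.n_tumours
        for g in (g1, g2):
            est = c.density[g]
            total[g] = (total[g][0] + est.count, est.effective_bp)
    r1 = total[g1][0] / (total[g1][1] * n_total)
    r2 = total[g2][0] / (total[g2][1] * n_total)
    fisher.depletion = depletion_fraction(r1, r2)
    return fisher


def flank_core_study(
    muts: pd.DataFrame,
    exons,
    genome,
    samples_by_cohort: dict,
    flank_len: int = 20,
    core_len: int = 40,
    end_exclusion: int = 0,
    cpg_mask: bool = False,
    consequence: str = "synonymous",
    B: int = 500,
    confidence: float = 0.95,
    seed: int = 0,
) -> StudyResult:
    """The flank-vs-core battery over one or more cohorts.

    ``samples_by_cohort`` maps cohort name to the full tumour list
    (zero-mutation tumours dilute rates, as in per-cohort averaging).
    """
    region_set = build_flank_core_region_set(exons, flank_len, core_len, end_exclusion)
    mask = cpg_mask_for_region_set(genome, region_set) if cpg_mask else set()
    region_set.masked_positions = mask
    muts = _filter_consequence(muts, consequence)
    groups = {"flank": ("flank5", "flank3"), "core": ("core",)}
    cohorts = []
    tables = []
    for name, samples in samples_by_cohort.items():
        sub = muts[muts["sample_id"].isin(samples)]
        c = _cohort_result(name, sub, region_set, mask, samples, groups, B, confidence, seed)
        tables.append(c._per_tumour.assign(cohort=name))
        cohorts.append(c)
    combined = _combine(cohorts, "flank", "core")
    return StudyResult(
        cohorts=cohorts,
        combined=combined,
        per_tumour=pd.concat(tables, ignore_index=True),
        region_set=region_set,
        groups=("flank", "core"),
    )


def build_ese_region_set(
    exons,
    genome,
    ese_hexamers,
    end_window: int = 69,
    min_distance: int = 2,
    watson_only: bool = False,
    symmetric_discard: bool = True,
    non_ese_hexamers=None,
) -> RegionSet:
    """Scan exon coding-strand sequence for ESE / non-ESE regions.

    Matches are restricted to the terminal ``end_window`` bp of each
    exon, merged within a set, cross-set overlaps discarded, and mapped
    back to genome coordinates.
    """
    if non_ese_hexamers is None:
        non_ese_hexamers = build_non_ese_set(ese_hexamers, min_distance=min_distance)
    if not non_ese_hexamers.members:
        raise ValueError("non-ESE set is empty after distance filtering")
    intervals = []
    for exon in exons:
        if watson_only and exon.strand != "+":
            continue
        seq = fetch(genome, exon.chrom, exon.start, exon.end)
        if exon.strand == "-":
            seq = revcomp(seq)
        ese_regions = scan_hexamer_regions(seq, ese_hexamers, end_window, role="ese")
        non_regions = scan_hexamer_regions(seq, non_ese_hexamers, end_window, role="non_ese")
        ese_regions, non_regions = resolve_overlaps(
            ese_regions, non_regions, symmetric=symmetric_discard
        )
        for region in ese_regions + non_regions:
            g_start, g_end = exon_relative_to_genome(exon, region.start, region.end)
            intervals.append(
                GenomicInterval(exon.chrom, g_start, g_end, exon.strand, region.role, exon)
            )
    return RegionSet(intervals=intervals)


def ese_study(
    muts: pd.DataFrame,
    exons,
    genome,
    ese_hexamers,
    samples_by_cohort: dict,
    end_window: int = 69,
    min_distance: int = 2,
    watson_only: bool = False,
    cpg_mask: bool = False,
    consequence: str = "synonymous",
    B: int = 500,
    confidence: float = 0.95,
    seed: int = 0,
) -> StudyResult:
    """The ESE-vs-non-ESE battery (same statistics as flank/core)."""
    region_set = build_ese_region_set(
        exons, genome, ese_hexamers, end_window, min_distance, watson_only
    )
    if not any(iv.role == "ese" for iv in region_set.intervals):
        raise ValueError("no ESE regions found; check the hexamer list and exons")
    mask = cpg_mask_for_region_set(genome, region_set) if cpg_mask else set()
    region_set.masked_positions = mask
    muts = _filter_consequence(muts, consequence)
    groups = {"ese": ("ese",), "non_ese": ("non_ese",)}
    cohorts = []
    tables = []
    for name, samples in samples_by_cohort.items():
        sub = muts[muts["sample_id"].isin(samples)]
        c = _cohort_result(name, sub, region_set, mask, samples, groups, B, confidence, seed)
        tables.append(c._per_tumour.assign(cohort=name))
        cohorts.append(c)
    combined = _combine(cohorts, "ese", "non_ese")
    return StudyResult(
        cohorts=cohorts,
        combined=combined,
        per_tumour=pd.concat(tables, ignore_index=True),
        region_set=region_set,
        groups=("ese", "non_ese"),
    )
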