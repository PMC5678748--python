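"""SSM counting, density estimation and composition-normalized rates.

The density unit throughout is mutations per base pair per tumour:
``rate = count / (effective_bp * n_tumours)``. Effective bp discounts
masked positions (CpG masking); a mutation at a masked position is
excluded from the numerator and its base from the denominator.

Class-normalized rates divide the count of a canonical substitution
class X>Y by the number of X plus complement(X) bases in the region's
sequence (both-strand collapse); trinucleotide rates use the analogous
reference-triplet occurrence denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import fetch, revcomp
from .intervals import RegionSet
from .mutations import (
    SIX_CLASSES,
    all_trinucleotide_classes,
    canonical_substitution_class,
    trinucleotide_class,
)
from .stats import bootstrap_mean_ci

logger = logging.getLogger(__name__)


@dataclass
class DensityEstimate:
    """Pooled SSM density for one region role."""

    count: int
    effective_bp: int
    n_tumours: int
    rate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def mask_cpg_positions(genome, interval) -> set:
    """Genome positions inside ``interval`` participating in a CG dinucleotide.

    Context is read 1 bp beyond each interval edge, so a terminal C
    whose G lies just outside the interval is still masked; at contig
    edges the missing side contributes no mask.
    """
    lo = max(0, interval.start - 1)
    hi = min(len(genome[interval.chrom]), interval.end + 1)
    seq = fetch(genome, interval.chrom, lo, hi)
    masked = set()
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            for p in (lo + i, lo + i + 1):
                if interval.start <= p < interval.end:
                    masked.add(p)
    return masked


def cpg_mask_for_region_set(genome, region_set: RegionSet) -> set:
    """Union CpG mask over all intervals, as ``(chrom, pos)`` pairs."""
    masked = set()
    for iv in region_set.intervals:
        for p in mask_cpg_positions(genome, iv):
            masked.add((iv.chrom, p))
    return masked


def position_role_map(region_set: RegionSet) -> dict:
    """(chrom, pos) -> role; errors if any base is claimed twice."""
    mapping = {}
    for iv in region_set.intervals:
        for p in range(iv.start, iv.end):
            key = (iv.chrom, p)
            if key in mapping:
                raise ValueError(
                    f"position {iv.chrom}:{p} in overlapping regions "
                    f"({mapping[key]} and {iv.role})"
                )
            mapping[key] = iv.role
    return mapping


def _effective_bp_by_role(region_set: RegionSet, mask) -> dict:
    out = {}
    for iv in region_set.intervals:
        eff = len(iv)
        if mask:
            eff -= sum(1 for p in range(iv.start, iv.end) if (iv.chrom, p) in mask)
        out[iv.role] = out.get(iv.role, 0) + eff
    return out


def count_mutations_in_regions(muts: pd.DataFrame, region_set: RegionSet, mask=None):
    """Per-role SSM counts and effective bp.

    ``muts`` is the tidy mutation frame (sample_id, chrom, pos, ...).
    Mutations at masked positions are excluded; mutations outside every
    region are ignored. Returns role -> (count, effective_bp).
    """
    mask = mask or set()
    role_of = position_role_map(region_set)
    eff = _effective_bp_by_role(region_set, mask)
    counts = {role: 0 for role in eff}
    for chrom, pos in zip(muts["chrom"].to_numpy(), muts["pos"].to_numpy()):
        key = (chrom, int(pos))
        if key in mask:
            continue
        role = role_of.get(key)
        if role is not None:
            counts[role] += 1
    return {role: (counts[role], eff[role]) for role in eff}


def ssm_density(count: int, effective_bp: int, n_tumours: int) -> DensityEstimate:
    """Pooled rate per bp per tumour."""
    if effective_bp <= 0 or n_tumours <= 0:
        raise ValueError("effective_bp and n_tumours must be positive")
    return DensityEstimate(
        count=count,
        effective_bp=effective_bp,
        n_tumours=n_tumours,
        rate=count / (effective_bp * n_tumours),
    )


def per_tumour_density_table(
    muts: pd.DataFrame, region_set: RegionSet, mask=None, samples=None
) -> pd.DataFrame:
    """One row per tumour per role, explicit zeros included.

    ``samples`` fixes the tumour universe (tumours with no mutation in
    any region appear with zero counts); by default it is the set of
    samples present in ``muts``.
    """
    mask = mask or set()
    role_of = position_role_map(region_set)
    eff = _effective_bp_by_role(region_set, mask)
    if samples is None:
        samples = sorted(muts["sample_id"].unique())
    samples = list(samples)
    roles = sorted(eff)
    counts = {(s, r): 0 for s in samples for r in roles}
    known = set(samples)
    for sample, chrom, pos in zip(
        muts["sample_id"].to_numpy(), muts["chrom"].to_numpy(), muts["pos"].to_numpy()
    ):
        if sample not in known:
            continue
        key = (chrom, int(pos))
        if key in mask:
            continue
        role = role_of.get(key)
        if role is not None:
            counts[(sample, role)] += 1
    rows = []
    for s in samples:
        for r in roles:
            c = counts[(s, r)]
            rows.append((s, r, c, eff[r], c / eff[r] if eff[r] else float("nan")))
    return pd.DataFrame(rows, columns=["sample_id", "role", "count", "effective_bp", "rate"])


def _role_base_positions(region_set: RegionSet, mask):
    """Per role: list of (chrom, pos) of unmasked bases."""
    mask = mask or set()
    out = {}
    for iv in region_set.intervals:
        lst = out.setdefault(iv.role, [])
        for p in range(iv.start, iv.end):
            if (iv.chrom, p) not in mask:
                lst.append((iv.chrom, p))
    return out


def class_normalized_rates(
    muts: pd.DataFrame, region_set: RegionSet, genome, n_tumours: int, mask=None
) -> pd.DataFrame:
    """Per (role, class) rates normalized by eligible reference bases.

    The denominator for class X>Y is the number of X plus complement(X)
    bases among the role's unmasked positions, times ``n_tumours``.
    Classes with no eligible bases get a NaN rate and are flagged in the
    ``defined`` column.
    """
    mask = mask or set()
    role_of = position_role_map(region_set)
    base_pos = _role_base_positions(region_set, mask)
    rows = []
    counts = {}
    for chrom, pos, ref, alt in zip(
        muts["chrom"].to_numpy(), muts["pos"].to_numpy(),
        muts["ref"].to_numpy(), muts["alt"].to_numpy(),
    ):
        key = (chrom, int(pos))
        if key in mask:
            continue
        role = role_of.get(key)
        if role is None:
            continue
        cls = canonical_substitution_class(ref, alt)
        counts[(role, cls)] = counts.get((role, cls), 0) + 1
    for role, positions in sorted(base_pos.items()):
        tallies = {b: 0 for b in "ACGT"}
        for chrom, p in positions:
            tallies[fetch(genome, chrom, p, p + 1)] += 1
        pair = {
            "A": tallies["A"] + tallies["T"],
            "C": tallies["C"] + tallies["G"],
            "G": tallies["G"] + tallies["C"],
        }
        for cls in SIX_CLASSES:
            denom_bases = pair[cls[0]]
            count = counts.get((role, cls), 0)
            if denom_bases == 0:
                logger.warning("role %s class %s has no eligible bases", role, cls)
                rate, defined = float("nan"), False
            else:
                rate, defined = count / (denom_bases * n_tumours), True
            rows.append((role, cls, count, denom_bases, n_tumours, rate, defined))
    return pd.DataFrame(
        rows,
        columns=["role", "subst_class", "count", "denom_bases", "n_tumours", "rate", "defined"],
    )


def trinuc_rates(
    muts: pd.DataFrame, region_set: RegionSet, genome, n_tumours: int, mask=None
) -> pd.DataFrame:
    """Per (role, trinucleotide class) rates.

    Numerators classify each in-region SSM by its canonical trinuc
    label; denominators count occurrences of the class's reference
    triplet (plus its reverse complement) among the role's unmasked
    positions, using genome context across interval edges. Records
    whose context is unavailable (contig edge, N) are excluded and
    logged.
    """
    mask = mask or set()
    role_of = position_role_map(region_set)
    base_pos = _role_base_positions(region_set, mask)
    counts = {}
    n_excluded = 0
    for chrom, pos, ref, alt in zip(
        muts["chrom"].to_numpy(), muts["pos"].to_numpy(),
        muts["ref"].to_numpy(), muts["alt"].to_numpy(),
    ):
        key = (chrom, int(pos))
        if key in mask:
            continue
        role = role_of.get(key)
        if role is None:
            continue
        try:
            label = trinucleotide_class(genome, chrom, int(pos), ref, alt)
        except ValueError:
            n_excluded += 1
            continue
        counts[(role, label)] = counts.get((role, label), 0) + 1
    if n_excluded:
        logger.info("excluded %d SSMs without full trinucleotide context", n_excluded)

    rows = []
    labels = all_trinucleotide_classes()
    for role, positions in sorted(base_pos.items()):
        triplet_tally = {}
        for chrom, p in positions:
            contig = genome[chrom]
            n = len(contig)
            if p < 1 or p + 1 >= n:
                continue
            tri = fetch(genome, chrom, p - 1, p + 2)
            if "N" in tri:
                continue
            triplet_tally[tri] = triplet_tally.get(tri, 0) + 1
        for label in labels:
            ref_tri = label[0] + label[2] + label[6]
            denom = triplet_tally.get(ref_tri, 0) + triplet_tally.get(revcomp(ref_tri), 0)
            count = counts.get((role, label), 0)
            if denom == 0:
                rate, defined = float("nan"), False
            else:
                rate, defined = count / (denom * n_tumours), True
            rows.append((role, label, count, denom, n_tumours, rate, defined))
    return pd.DataFrame(
        rows,
        columns=["role", "trinuc_class", "count", "denom_trinucs", "n_tumours", "rate", "defined"],
    )


def depletion_fraction(flank_rate: float, core_rate: float) -> float:
    """1 - flank/core: the share of flank mutational events unobservable
    under the assumption that the core rate is the true mutation rate.
    Negative when the flank rate exceeds the core rate."""
    if core_rate == 0:
        raise ValueError("core rate is zero")
    return 1.0 - flank_rate / core_rate


def region_mean_score(per_base_scores: pd.DataFrame, region_set: RegionSet):
    """Mean of a per-base score (e.g. mappability) per role and per interval.

    ``per_base_scores`` columns: chrom, pos, score. Uncovered bases are
    excluded; coverage fractions are logged. Returns
    ``(role -> mean, per-interval DataFrame)``.
    """
    score_of = {
        (c, int(p)): float(s)
        for c, p, s in zip(
            per_base_scores["chrom"].to_numpy(),
            per_base_scores["pos"].to_numpy(),
            per_base_scores["score"].to_numpy(),
        )
    }
    rows = []
    sums = {}
    for i, iv in enumerate(region_set.intervals):
        vals = [score_of[(iv.chrom, p)] for p in range(iv.start, iv.end) if (iv.chrom, p) in score_of]
        covered = len(vals)
        if covered < len(iv):
            logger.info(
                "interval %s:%d-%d coverage %.2f", iv.chrom, iv.start, iv.end, covered / len(iv)
            )
        mean = float(np.mean(vals)) if vals else float("nan")
        rows.append((i, iv.chrom, iv.start, iv.end, iv.role, covered, mean))
        if vals:
            tot, n = sums.get(iv.role, (0.0, 0))
            sums[iv.role] = (tot + sum(vals), n + covered)
    role_means = {role: tot / n for role, (tot, n) in sums.items() if n}
    table = pd.DataFrame(
        rows, columns=["interval", "chrom", "start", "end", "role", "covered_bp", "mean_score"]
    )
    return role_means, table


def attach_bootstrap_ci(
    estimate: DensityEstimate, per_tumour_rates, B: int = 500,
    confidence: float = 0.95, seed: int = 0
) -> DensityEstimate:
    """Percentile bootstrap CI of the mean per-tumour rate (B resamples)."""
    _, lo, hi = bootstrap_mean_ci(per_tumour_rates, B=B, confidence=confidence, seed=seed)
    estimate.ci_low, estimate.ci_high = lo, hi
    return estimate
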