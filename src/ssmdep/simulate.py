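"""Synthetic genomes, transcript models and tumour cohorts with known
region-dependent purifying selection.

The generative model mirrors the Selection Model the analysis is built
to detect: mutations arise uniformly across exons (per-site probability
``mu`` per tumour, optionally scaled at CpG sites and shaped by a
six-class substitution signature) and are then *purged* — removed
before observation — with a probability that depends on the region the
site falls in (``purge_flank`` for the terminal 20 bp of internal
exons, ``purge_ese`` for planted splice-enhancer motifs) and on the
gene class (e.g. no purging in tumour suppressors). Purging is
independent thinning of arisen mutations, which is exactly the quantity
the pipeline's depletion fraction estimates.

Defaults are deliberately composition-neutral (uniform signature, CpG
multiplier 1) so that the null model has a uniform per-base mutation
rate; hypermutability and signature skew are opt-in knobs.

The planted ESE motif alphabet is purine-only hexamers; each planted
motif sits inside a guard context (4 purines + 1 pyrimidine on each
side) so that every scan window overlapping a planted match is within
Hamming distance 1 of the ESE set. Without such clustering, isolated
motifs in random sequence are always flanked by control-set matches and
the overlap-discard rule removes them — see docs/methods.md.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import BASE_INDEX, BASES, revcomp
from .hexamers import HexamerSet
from .intervals import (
    ExonContext,
    GenomicInterval,
    TranscriptModel,
    build_flank_core_region_set,
    exon_relative_to_genome,
    select_internal_coding_exons,
)
from .mutations import SIX_CLASSES, ConsequenceAnnotator, canonical_substitution_class

logger = logging.getLogger(__name__)

UNIFORM_SIGNATURE = {c: 1.0 / 6.0 for c in SIX_CLASSES}

REGION_CLASSES = ("other", "core", "flank", "ese", "flank_ese")


@dataclass
class SimulationParams:
    """Generator knobs; probabilities in [0, 1], signature sums to 1."""

    n_genes: int = 60
    exons_per_gene: int = 5
    exon_length: tuple = (200, 280)        # sampled uniformly, >= 160
    gc_content: float = 0.5
    ese_plant_rate: float = 1.0            # expected planted motifs per end zone
    mu: float = 1e-3                       # per-base per-tumour mutation probability
    cpg_multiplier: float = 1.0
    signature: dict = field(default_factory=lambda: dict(UNIFORM_SIGNATURE))
    purge_flank: float = 0.0
    purge_ese: float = 0.0
    gene_class_overrides: dict = field(default_factory=dict)  # class -> purge multiplier
    n_tumours: int = 100
    seed: int = 0
    intron_length: int = 80
    intergenic_length: int = 100
    chrom: str = "chr1"
    flank_len: int = 20
    end_window: int = 69

    def __post_init__(self):
        for name in ("gc_content", "mu", "cpg_multiplier", "purge_flank", "purge_ese"):
            v = getattr(self, name)
            if name == "cpg_multiplier":
                if v < 0:
                    raise ValueError("cpg_multiplier must be >= 0")
            elif not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.exon_length[0] < 160:
            raise ValueError("exon lengths must be >= 160")
        total = sum(self.signature.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signature weights sum to {total}, not 1")


@dataclass
class SimTruth:
    """Ground-truth bookkeeping: arisen / purged / retained per region class."""

    arisen: dict = field(default_factory=dict)
    purged: dict = field(default_factory=dict)
    core_class_counts: dict = field(default_factory=dict)  # six-class, retained in core

    def retained(self, region_class: str) -> int:
        return self.arisen.get(region_class, 0) - self.purged.get(region_class, 0)

    def realized_depletion(self, region_class: str) -> float:
        n = self.arisen.get(region_class, 0)
        return self.purged.get(region_class, 0) / n if n else float("nan")


_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")


def default_ese_hexamers() -> HexamerSet:
    """The synthetic stand-in ESE catalogue: 84 hexamers.

    All 64 purine hexamers (the planted motif alphabet) plus 20
    two-cytosine hexamers, matching the size of intersection-style ESE
    catalogues. Deterministic; disjoint from any >= 2-distance control
    set by construction. The extras carry two pyrimidines so that their
    isolated matches in random sequence stay flanked by control-set
    windows (and are removed by the overlap rule) instead of inflating
    the unpurged share of scanned ESE bases.
    """
    purine = ["".join(p) for p in itertools.product(_PURINES, repeat=6)]
    extras = []
    for i, h in enumerate(sorted(purine)):
        if len(extras) >= 20:
            break
        pos = i % 5
        cand = h[:pos] + "C" + h[pos + 1 : pos + 4] + "C" + h[pos + 5:]
        if cand not in extras and len(cand) == 6:
            extras.append(cand)
    return HexamerSet(members=frozenset(purine + extras), provenance="ese")


def _random_seq(rng, length, gc):
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])


def generate_genome_and_transcripts(params: SimulationParams, rng=None):
    """Build the synthetic genome, transcript table and planted-ESE intervals.

    Returns ``(genome dict, transcripts, planted)`` where ``planted``
    holds genome-coordinate intervals (role ``ese``) of planted motifs.
    Gene structures: ``exons_per_gene`` coding exons separated by
    introns, genes separated by intergenic spacers, random strand, CDS
    length padded to a codon multiple.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    purine_motifs = sorted(default_ese_hexamers().members & {
        "".join(p) for p in itertools.product(_PURINES, repeat=6)
    })
    chunks = []
    cursor = 0
    transcripts = []
    planted = []
    for g in range(params.n_genes):
        chunks.append(_random_seq(rng, params.intergenic_length, params.gc_content))
        cursor += params.intergenic_length
        strand = "+" if rng.random() < 0.5 else "-"
        lengths = [
            int(rng.integers(params.exon_length[0], params.exon_length[1] + 1))
            for _ in range(params.exons_per_gene)
        ]
        remainder = sum(lengths) % 3
        if remainder:
            lengths[-1] += 3 - remainder
        exons = []
        exon_seqs = []
        for e, length in enumerate(lengths):
            if e:
                chunks.append(_random_seq(rng, params.intron_length, params.gc_content))
                cursor += params.intron_length
            seq = list(_random_seq(rng, length, params.gc_content))
            genomic_internal = 0 < e < params.exons_per_gene - 1
            if genomic_internal and params.ese_plant_rate > 0:
                seq, spans = _plant_motifs(
                    rng, seq, params.ese_plant_rate, params.end_window,
                    purine_motifs, strand,
                )
                for rel_start, rel_end in spans:
                    if strand == "+":
                        g_start, g_end = cursor + rel_start, cursor + rel_end
                    else:
                        # rel coords are coding-strand; mirror within the exon
                        g_start = cursor + length - rel_end
                        g_end = cursor + length - rel_start
                    planted.append(
                        GenomicInterval(params.chrom, g_start, g_end, strand, "ese")
                    )
            chunks.append("".join(seq))
            exons.append((cursor, cursor + length))
            cursor += length
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{g:04d}",
                gene_id=f"gene{g:04d}",
                chrom=params.chrom,
                strand=strand,
                coding_exons=tuple(exons),
            )
        )
    chunks.append(_random_seq(rng, params.intergenic_length, params.gc_content))
    genome = {params.chrom: "".join(chunks)}
    return genome, transcripts, planted


def _plant_motifs(rng, seq_list, rate, end_window, motifs, strand):
    """Plant guarded purine motifs in the coding-strand end zones.

    ``seq_list`` is the genome-strand exon sequence as a list; planting
    coordinates are coding-strand relative, so for ``-`` genes the
    template is reverse-complemented and mirrored into the genome
    sequence. Returns the modified list and coding-relative motif spans.
    """
    L = len(seq_list)
    template_len = 16  # 4R + Y + motif(6) + Y + 4R
    spans = []
    occupied = []
    for zone_start, zone_end in ((0, end_window), (L - end_window, L)):
        hi = zone_end - template_len
        if hi <= zone_start:
            continue
        for _ in range(rng.poisson(rate)):
            t0 = int(rng.integers(zone_start, hi + 1))
            if any(t0 < e and s < t0 + template_len for s, e in occupied):
                continue  # collision: skip rather than stack motifs
            occupied.append((t0, t0 + template_len))
            motif = motifs[rng.integers(len(motifs))]
            guard_l = "".join(rng.choice(_PURINES, 4))
            guard_r = "".join(rng.choice(_PURINES, 4))
            template = (
                guard_l + rng.choice(_PYRIMIDINES) + motif
                + rng.choice(_PYRIMIDINES) + guard_r
            )
            if strand == "+":
                seq_list[t0 : t0 + template_len] = list(template)
            else:
                g0 = L - (t0 + template_len)
                seq_list[g0 : g0 + template_len] = list(revcomp(template))
            spans.append((t0 + 5, t0 + 11))
    return seq_list, spans


def build_purge_region_map(annotator, flank_regions=None, ese_regions=None):
    """Per-site region-class codes for the simulator.

    Returns an int array over the annotator's sites: index into
    ``REGION_CLASSES`` (other / core / flank / ese / flank_ese).
    ``flank_regions`` and ``ese_regions`` are interval lists; cores are
    derived from flank construction when provided as a RegionSet.
    """
    codes = np.zeros(annotator.n_sites, dtype=np.int8)
    by_key = {(c, int(p)): i for i, (c, p) in enumerate(zip(annotator.chrom, annotator.pos))}

    def paint(intervals, kind):
        for iv in intervals:
            for p in range(iv.start, iv.end):
                i = by_key.get((iv.chrom, p))
                if i is None:
                    continue
                if kind == "core":
                    if codes[i] == 0:
                        codes[i] = 1
                elif kind == "flank":
                    codes[i] = 4 if codes[i] == 3 else 2
                elif kind == "ese":
                    codes[i] = 4 if codes[i] == 2 else 3

    if flank_regions is not None:
        flanks = [iv for iv in flank_regions if iv.role in ("flank5", "flank3")]
        cores = [iv for iv in flank_regions if iv.role == "core"]
        paint(flanks, "flank")
        paint(cores, "core")
    if ese_regions is not None:
        paint(ese_regions, "ese")
    return codes


def simulate_cohort(
    genome,
    transcripts,
    params: SimulationParams,
    region_codes=None,
    annotator=None,
    gene_classes=None,
    rng=None,
    sample_prefix: str = "T",
):
    """Simulate one tumour cohort; returns ``(maf_frame, SimTruth)``.

    ``region_codes`` is the per-site region-class array from
    :func:`build_purge_region_map` (None = no purging anywhere).
    ``gene_classes`` maps gene_id to a label whose entry in
    ``params.gene_class_overrides`` multiplies the purge probability.
    At most one mutation arises per site per tumour. The returned frame
    has MAF columns with 1-based positions and a recomputed
    Variant_Classification.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if annotator is None:
        annotator = ConsequenceAnnotator(transcripts, genome)
    n = annotator.n_sites
    if region_codes is None:
        region_codes = np.zeros(n, dtype=np.int8)

    # per-site hazard: mu scaled by signature mass applicable to the ref base
    w = params.signature
    s_base = np.array([
        w["A>C"] + w["A>G"] + w["A>T"],   # A
        w["C>G"] + w["C>T"] + w["G>T"],   # C (incl. C>A == G>T class)
        w["C>G"] + w["C>T"] + w["G>T"],   # G (G>C, G>A, G>T)
        w["A>C"] + w["A>G"] + w["A>T"],   # T
    ])
    p_site = 2.0 * params.mu * s_base[annotator.ref_code]

    # CpG scaling: both bases of a CG dinucleotide on the genome strand
    if params.cpg_multiplier != 1.0:
        chrom_seq = {c: genome[c] for c in set(annotator.chrom.tolist())}
        cpg = np.zeros(n, dtype=bool)
        for i in range(n):
            c, p = annotator.chrom[i], int(annotator.pos[i])
            seq = chrom_seq[c]
            b = seq[p]
            if (b == "C" and p + 1 < len(seq) and seq[p + 1] == "G") or (
                b == "G" and p > 0 and seq[p - 1] == "C"
            ):
                cpg[i] = True
        p_site = np.where(cpg, np.minimum(1.0, p_site * params.cpg_multiplier), p_site)

    # per-site alternate-allele distribution (3 alts, weights by class)
    alt_codes = np.zeros((4, 3), dtype=np.int8)
    alt_cum = np.zeros((4, 3))
    for ref_i, ref in enumerate(BASES):
        alts = [a for a in range(4) if a != ref_i]
        weights = np.array([
            w[canonical_substitution_class(ref, BASES[a])] for a in alts
        ])
        weights = weights / weights.sum()
        alt_codes[ref_i] = alts
        alt_cum[ref_i] = np.cumsum(weights)
    site_alt_codes = alt_codes[annotator.ref_code]
    site_alt_cum = alt_cum[annotator.ref_code]

    # per-site purge probability
    purge_base = np.zeros(n)
    purge_base[region_codes == 2] = params.purge_flank
    purge_base[region_codes == 3] = params.purge_ese
    purge_base[region_codes == 4] = max(params.purge_flank, params.purge_ese)
    if gene_classes and params.gene_class_overrides:
        mult = np.ones(n)
        for i in range(n):
            label = gene_classes.get(annotator.gene_of_site(i))
            if label in params.gene_class_overrides:
                mult[i] = params.gene_class_overrides[label]
        purge_base = purge_base * mult

    truth = SimTruth(
        arisen={c: 0 for c in REGION_CLASSES},
        purged={c: 0 for c in REGION_CLASSES},
        core_class_counts={c: 0 for c in SIX_CLASSES},
    )
    class_code = np.zeros((4, 4), dtype=np.int8)
    for r in range(4):
        for a in range(4):
            if r != a:
                class_code[r, a] = SIX_CLASSES.index(
                    canonical_substitution_class(BASES[r], BASES[a])
                )

    frames = {k: [] for k in ("sample", "pos_idx", "alt")}
    for t in range(params.n_tumours):
        hits = np.nonzero(rng.random(n) < p_site)[0]
        if hits.size == 0:
            continue
        r = rng.random(hits.size)
        which = (r[:, None] > site_alt_cum[hits]).sum(axis=1)
        which = np.minimum(which, 2)
        alt = site_alt_codes[hits, which]
        purged = rng.random(hits.size) < purge_base[hits]

        arisen_by_class = np.bincount(region_codes[hits], minlength=5)
        purged_by_class = np.bincount(region_codes[hits[purged]], minlength=5)
        for ci, name in enumerate(REGION_CLASSES):
            truth.arisen[name] += int(arisen_by_class[ci])
            truth.purged[name] += int(purged_by_class[ci])

        keep = ~purged
        kept_idx = hits[keep]
        kept_alt = alt[keep]
        core_kept = region_codes[kept_idx] == 1
        if core_kept.any():
            cls = class_code[annotator.ref_code[kept_idx[core_kept]], kept_alt[core_kept]]
            for ci, cnt in zip(*np.unique(cls, return_counts=True)):
                truth.core_class_counts[SIX_CLASSES[ci]] += int(cnt)
        frames["sample"].append(np.full(kept_idx.size, t, dtype=np.int32))
        frames["pos_idx"].append(kept_idx)
        frames["alt"].append(kept_alt)

    if not frames["sample"]:
        logger.warning("no mutations retained; mu may be too small")
        empty = pd.DataFrame(columns=list(_MAF_OUT_COLUMNS))
        return empty, truth

    sample_idx = np.concatenate(frames["sample"])
    pos_idx = np.concatenate(frames["pos_idx"])
    alt_code = np.concatenate(frames["alt"])
    base_arr = np.array(list(BASES))
    cons_code = annotator.cons[pos_idx, alt_code]
    classification = np.where(
        cons_code == 0, "Silent",
        np.where(cons_code == 1, "Missense_Mutation", "RNA"),
    )
    genes = np.array([t.gene_id for t in annotator.transcripts])[annotator.t_index[pos_idx]]
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": genes,
            "Chromosome": annotator.chrom[pos_idx],
            "Start_Position": annotator.pos[pos_idx] + 1,
            "Reference_Allele": base_arr[annotator.ref_code[pos_idx]],
            "Tumor_Seq_Allele2": base_arr[alt_code],
            "Variant_Classification": classification,
            "Variant_Type": "SNP",
            "Tumor_Sample_Barcode": np.char.add(
                f"{sample_prefix}", np.char.zfill(sample_idx.astype(str), 4)
            ),
        }
    )
    return maf, truth


_MAF_OUT_COLUMNS = (
    "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "Variant_Type",
    "Tumor_Sample_Barcode",
)


def maf_to_frame(maf: pd.DataFrame) -> pd.DataFrame:
    """Tidy mutation frame (0-based) from a simulated MAF frame."""
    cons = maf["Variant_Classification"].map(
        {"Silent": "synonymous", "Missense_Mutation": "non_synonymous"}
    ).fillna("other")
    return pd.DataFrame(
        {
            "sample_id": maf["Tumor_Sample_Barcode"].to_numpy(),
            "chrom": maf["Chromosome"].to_numpy(),
            "pos": maf["Start_Position"].to_numpy(dtype=int) - 1,
            "ref": maf["Reference_Allele"].to_numpy(),
            "alt": maf["Tumor_Seq_Allele2"].to_numpy(),
            "consequence": cons.to_numpy(),
            "gene_id": maf["Hugo_Symbol"].to_numpy(),
        }
    )


def cohort_sample_ids(params: SimulationParams, sample_prefix: str = "T"):
    return [f"{sample_prefix}{i:04d}" for i in range(params.n_tumours)]


def make_covariate_fixtures(
    transcripts,
    seed: int = 0,
    n_samples: int = 0,
    tsg_fraction: float = 0.1,
    oncogene_fraction: float = 0.1,
    essential_fraction: float = 0.3,
    msi_fraction: float = 0.2,
    min_exon: int = 160,
):
    """Null covariate tables for the stratification inputs.

    Exon scores (nucleosome occupancy, replication timing, mappability)
    are uniform draws with zero built-in correlation to flank/core
    identity; gene and sample labels follow the given class fractions.
    Deterministic under ``seed``. Returns a dict of DataFrames keyed
    ``exon_scores``, ``gene_classes``, ``samples``.
    """
    rng = np.random.default_rng(seed)
    exons = select_internal_coding_exons(transcripts, min_length=min_exon)
    exon_rows = [
        (e.key, rng.uniform(), rng.uniform(), rng.uniform(0.9, 1.0)) for e in exons
    ]
    exon_scores = pd.DataFrame(
        exon_rows, columns=["exon", "nucleosome", "replication_timing", "mappability"]
    )
    gene_rows = []
    for t in transcripts:
        u = rng.uniform()
        if u < tsg_fraction:
            cancer = "tumour_suppressor"
        elif u < tsg_fraction + oncogene_fraction:
            cancer = "oncogene"
        else:
            cancer = "non_cancer"
        ess = "essential" if rng.uniform() < essential_fraction else "non_essential"
        gene_rows.append((t.gene_id, cancer, ess))
    gene_classes = pd.DataFrame(
        gene_rows, columns=["gene_id", "cancer_class", "essentiality"]
    )
    sample_rows = [
        (f"T{i:04d}", "MSI" if rng.uniform() < msi_fraction else "MSS", "cohort1")
        for i in range(n_samples)
    ]
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "msi_status", "cohort"])
    return {"exon_scores": exon_scores, "gene_classes": gene_classes, "samples": samples}


def write_fasta(genome: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genepred(transcripts, path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            starts = ",".join(str(s) for s, _ in t.coding_exons) + ","
            ends = ",".join(str(e) for _, e in t.coding_exons) + ","
            tx_start = t.coding_exons[0][0]
            tx_end = t.coding_exons[-1][1]
            fh.write(
                "\t".join(
                    [
                        t.transcript_id, t.chrom, t.strand,
                        str(tx_start), str(tx_end), str(tx_start), str(tx_end),
                        str(t.n_exons), starts, ends, t.gene_id,
                    ]
                )
                + "\n"
            )


def write_maf(maf: pd.DataFrame, path) -> None:
    maf.to_csv(path, sep="\t", index=False)
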