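"""Transcript models and exon flank/core interval construction.

The spatial unit of the analysis is the internal protein-coding exon of
length ``L >= 160`` bp. Each such exon is partitioned into a 20 bp
"flank" at each end and a 40 bp "core" centred on ``M = L // 2``. Flanks
are oriented by transcription direction: ``flank5`` is the end of the
exon that is transcribed first (the genomically left end on the ``+``
strand, the right end on ``-``). The core serves as the local baseline
for the mutation rate; the flanks carry splice-regulatory sequence.

All coordinates are 0-based half-open on the genome forward strand.
1-based input dialects (genePred-like tables, MAF) are converted at the
I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

ROLES = ("flank5", "flank3", "core", "ese", "non_ese")


@dataclass(frozen=True)
class TranscriptModel:
    """A single (canonical) transcript with its coding exon structure."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    coding_exons: tuple  # ordered ((start, end), ...) 0-based half-open

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.coding_exons:
            if end <= start:
                raise ValueError(
                    f"{self.transcript_id}: exon end {end} <= start {start}"
                )
            if start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.coding_exons)


@dataclass(frozen=True)
class ExonContext:
    """One coding exon of a transcript, with its ordinal position.

    ``is_internal`` is true iff the exon is neither the first nor the
    last coding exon of its transcript. ``M`` is the centre offset
    ``L // 2`` (integer centring for odd lengths).
    """

    parent: TranscriptModel
    ordinal: int

    @property
    def start(self) -> int:
        return self.parent.coding_exons[self.ordinal][0]

    @property
    def end(self) -> int:
        return self.parent.coding_exons[self.ordinal][1]

    @property
    def chrom(self) -> str:
        return self.parent.chrom

    @property
    def strand(self) -> str:
        return self.parent.strand

    @property
    def L(self) -> int:
        return self.end - self.start

    @property
    def M(self) -> int:
        return self.L // 2

    @property
    def is_internal(self) -> bool:
        return 0 < self.ordinal < self.parent.n_exons - 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass
class GenomicInterval:
    """A labelled half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    role: str = "core"
    exon_ref: ExonContext | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class RegionSet:
    """A collection of role-labelled intervals with optional masked positions.

    ``masked_positions`` holds ``(chrom, pos)`` genome coordinates (for
    example CpG positions); ``effective_bp`` discounts masked bases that
    fall inside the intervals.
    """

    intervals: list = field(default_factory=list)
    masked_positions: set = field(default_factory=set)

    @property
    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def effective_bp(self) -> int:
        return sum(v[1] for v in self.bp_by_role().values())

    def roles(self):
        return sorted({iv.role for iv in self.intervals})

    def bp_by_role(self) -> dict:
        """Per-role ``(total_bp, effective_bp)``."""
        out = {}
        for iv in self.intervals:
            tot, eff = out.get(iv.role, (0, 0))
            n_masked = 0
            if self.masked_positions:
                n_masked = sum(
                    1 for p in range(iv.start, iv.end) if (iv.chrom, p) in self.masked_positions
                )
            out[iv.role] = (tot + len(iv), eff + len(iv) - n_masked)
        return out


def _parse_genepred_row(fields, lineno):
    if len(fields) < 10:
        raise ValueError(f"line {lineno}: genePred row has {len(fields)} columns, need >= 10")
    name, chrom, strand = fields[0], fields[1], fields[2]
    try:
        cds_start, cds_end = int(fields[5]), int(fields[6])
        exon_starts = [int(x) for x in fields[8].rstrip(",").split(",") if x]
        exon_ends = [int(x) for x in fields[9].rstrip(",").split(",") if x]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric coordinate ({exc})") from None
    gene = fields[10] if len(fields) > 10 else name
    if len(exon_starts) != len(exon_ends):
        raise ValueError(f"line {lineno}: exonStarts/exonEnds length mismatch")
    exons = []
    for s, e in zip(exon_starts, exon_ends):
        if e < s:
            raise ValueError(f"line {lineno}: exon end {e} < start {s}")
        s2, e2 = max(s, cds_start), min(e, cds_end)
        if e2 > s2:
            exons.append((s2, e2))
    return name, gene, chrom, strand, exons


def _parse_bed12_row(fields, lineno):
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: BED12 row has {len(fields)} columns, need 12")
    chrom, name, strand = fields[0], fields[3], fields[5]
    try:
        tx_start = int(fields[1])
        tx_end = int(fields[2])
        thick_start, thick_end = int(fields[6]), int(fields[7])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric coordinate ({exc})") from None
    if tx_end < tx_start:
        raise ValueError(f"line {lineno}: end {tx_end} < start {tx_start}")
    if len(sizes) != len(offsets):
        raise ValueError(f"line {lineno}: blockSizes/blockStarts length mismatch")
    exons = []
    for size, off in zip(sizes, offsets):
        s, e = tx_start + off, tx_start + off + size
        if e < s:
            raise ValueError(f"line {lineno}: exon end {e} < start {s}")
        s2, e2 = max(s, thick_start), min(e, thick_end)
        if e2 > s2:
            exons.append((s2, e2))
    return name, name, chrom, strand, exons


def parse_transcript_table(path, dialect: str = "genepred"):
    """Parse a transcript table into :class:`TranscriptModel` objects.

    Supported dialects: ``genepred`` (name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds[, gene]) and
    ``bed12``. Exons are intersected with the CDS (thick) region, so the
    returned models carry coding exons only. Rows whose coding exon list
    is empty are skipped with a warning; malformed rows raise an error
    naming the line.
    """
    if dialect not in ("genepred", "bed12"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parser = _parse_genepred_row if dialect == "genepred" else _parse_bed12_row
    models = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, gene, chrom, strand, exons = parser(line.split("\t"), lineno)
            if not exons:
                n_skipped += 1
                logger.warning("line %d: transcript %s has no coding exons, skipped", lineno, name)
                continue
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=gene,
                    chrom=chrom,
                    strand=strand,
                    coding_exons=tuple(exons),
                )
            )
    if n_skipped:
        logger.info("skipped %d transcripts without coding exons", n_skipped)
    return models


def select_internal_coding_exons(models, min_length: int = 160):
    """Internal coding exons with length >= ``min_length`` (inclusive)."""
    out = []
    for model in models:
        for ordinal in range(model.n_exons):
            exon = ExonContext(parent=model, ordinal=ordinal)
            if exon.is_internal and exon.L >= min_length:
                out.append(exon)
    return out


def make_flank_core_regions(
    exon: ExonContext,
    flank_len: int = 20,
    core_len: int = 40,
    end_exclusion: int = 0,
) -> RegionSet:
    """Build the two flank intervals and the central core for one exon.

    Left flank ``[start+end_exclusion, start+flank_len)``, right flank
    ``[end-flank_len, end-end_exclusion)``, core
    ``[start+M-core_len/2, start+M+core_len/2)``. ``end_exclusion``
    trims the terminal bases carrying the canonical splice sites. Flank
    labels are provisional (left = flank5); apply :func:`orient_flanks`
    with the exon strand to fix them.
    """
    if core_len % 2:
        raise ValueError("core_len must be even")
    if end_exclusion >= flank_len:
        raise ValueError(f"end_exclusion {end_exclusion} >= flank_len {flank_len}")
    L, M = exon.L, exon.M
    if L < 2 * flank_len + core_len:
        raise ValueError(f"exon length {L} < 2*flank_len + core_len")
    start, end = exon.start, exon.end
    half = core_len // 2
    left = GenomicInterval(exon.chrom, start + end_exclusion, start + flank_len,
                           exon.strand, "flank5", exon)
    right = GenomicInterval(exon.chrom, end - flank_len, end - end_exclusion,
                            exon.strand, "flank3", exon)
    core = GenomicInterval(exon.chrom, start + M - half, start + M + half,
                           exon.strand, "core", exon)
    for flank in (left, right):
        if flank.overlaps(core):
            raise ValueError(f"flank {flank} overlaps core {core}")
    return RegionSet(intervals=[left, right, core])


def orient_flanks(region_set: RegionSet, strand: str) -> RegionSet:
    """Label the transcriptionally 5' flank ``flank5`` and the other ``flank3``.

    On ``+`` the genomically left flank is 5'; on ``-`` the right one
    is. Idempotent: orientation depends only on genomic position and
    strand, not on current labels.
    """
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    flanks = [iv for iv in region_set.intervals if iv.role in ("flank5", "flank3")]
    if len(flanks) != 2:
        raise ValueError(f"expected exactly 2 flank intervals, found {len(flanks)}")
    left, right = sorted(flanks, key=lambda iv: iv.start)
    if strand == "+":
        left_role, right_role = "flank5", "flank3"
    else:
        left_role, right_role = "flank3", "flank5"
    new_intervals = []
    for iv in region_set.intervals:
        if iv is left:
            new_intervals.append(replace(iv, role=left_role))
        elif iv is right:
            new_intervals.append(replace(iv, role=right_role))
        else:
            new_intervals.append(iv)
    return RegionSet(intervals=new_intervals, masked_positions=set(region_set.masked_positions))


def build_flank_core_region_set(
    exons,
    flank_len: int = 20,
    core_len: int = 40,
    end_exclusion: int = 0,
) -> RegionSet:
    """Oriented flank/core intervals for a collection of exons."""
    intervals = []
    for exon in exons:
        rs = make_flank_core_regions(exon, flank_len, core_len, end_exclusion)
        rs = orient_flanks(rs, exon.strand)
        intervals.extend(rs.intervals)
    return RegionSet(intervals=intervals)


def exon_relative_to_genome(exon: ExonContext, start: int, end: int):
    """Map a coding-strand exon-relative interval to genome coordinates."""
    if not 0 <= start < end <= exon.L:
        raise ValueError(f"interval ({start},{end}) outside exon of length {exon.L}")
    if exon.strand == "+":
        return exon.start + start, exon.start + end
    return exon.end - end, exon.end - start


def write_regions_bed(region_set: RegionSet, path) -> None:
    """Write a RegionSet as BED6 (role in the name column)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in region_set.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.role}\t0\t{iv.strand}\n")


def read_regions_bed(path) -> RegionSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: BED6 row has {len(fields)} columns")
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]),
                                fields[5], fields[3])
            )
    return RegionSet(intervals=intervals)
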