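"""Somatic mutation I/O, synonymous filtering and substitution classes.

Substitutions are collapsed with their reverse complements into six
canonical classes {A>C, A>G, A>T, C>G, C>T, G>T} (so T>G reports as A>C,
G>A as C>T, ...). Trinucleotide classes add the 5' and 3' reference
context, reverse-complementing the whole triplet when the central
substitution needs collapsing; 6 x 16 = 96 labels.

Consequence annotation compares amino acids of the reference and
alternate codons in coding orientation under the standard genetic code.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._seq import BASE_INDEX, BASES, complement, contig_length, fetch, revcomp

logger = logging.getLogger(__name__)

SIX_CLASSES = ("A>C", "A>G", "A>T", "C>G", "C>T", "G>T")

#: raw substitution -> canonical class
_CLASS_OF = {}
for _c in SIX_CLASSES:
    _r, _a = _c[0], _c[2]
    _CLASS_OF[(_r, _a)] = _c
    _CLASS_OF[(complement(_r), complement(_a))] = _c

CONSEQUENCES = ("synonymous", "non_synonymous", "other")

# MAF Variant_Classification -> consequence
_MAF_CONSEQUENCE = {
    "Silent": "synonymous",
    "Missense_Mutation": "non_synonymous",
    "Nonsense_Mutation": "non_synonymous",
    "Nonstop_Mutation": "non_synonymous",
}

MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "classification": "Variant_Classification",
    "variant_type": "Variant_Type",
    "gene_id": "Hugo_Symbol",
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant (0-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str = "other"
    gene_id: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")


def canonical_substitution_class(ref: str, alt: str) -> str:
    """Collapse a substitution and its reverse complement into one of six labels."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    return _CLASS_OF[(ref, alt)]


def trinucleotide_class(genome, chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical trinucleotide label, e.g. ``A[C>T]G``.

    If ``ref>alt`` is already canonical the flanking bases are read
    as-is; otherwise substitution and context are reverse-complemented
    together (5'/3' swap). Raises at contig edges and for N context
    (callers exclude and log such records).
    """
    if pos < 1 or pos + 1 >= contig_length(genome, chrom):
        raise ValueError(f"{chrom}:{pos} has no neighbour on one side")
    triplet = fetch(genome, chrom, pos - 1, pos + 2)
    if triplet[1] != ref:
        raise ValueError(f"genome base {triplet[1]} != ref {ref} at {chrom}:{pos}")
    if "N" in triplet:
        raise ValueError(f"N in context at {chrom}:{pos}")
    if f"{ref}>{alt}" in SIX_CLASSES:
        five, three, r, a = triplet[0], triplet[2], ref, alt
    else:
        five, three = complement(triplet[2]), complement(triplet[0])
        r, a = complement(ref), complement(alt)
    return f"{five}[{r}>{a}]{three}"


def all_trinucleotide_classes():
    """The 96 canonical trinucleotide labels."""
    out = []
    for cls in SIX_CLASSES:
        for five in BASES:
            for three in BASES:
                out.append(f"{five}[{cls}]{three}")
    return out


def read_mutations(path, dialect: str = "maf", column_map=None, genome=None):
    """Read somatic mutation calls into :class:`MutationRecord` objects.

    ``maf`` expects the standard MAF columns; ``column_map`` reads any
    TSV given a mapping from the logical fields (sample_id, chrom, pos,
    ref, alt, and optionally classification / consequence, gene_id) to
    column names. Input positions are 1-based and converted; indels,
    MNVs and multi-allelic rows are dropped with a logged count. When a
    genome is supplied, ref alleles are checked against it.
    """
    if dialect == "maf":
        colmap = dict(MAF_COLUMNS)
    elif dialect == "column_map":
        if not column_map:
            raise ValueError("column_map dialect requires a column map")
        colmap = dict(column_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for field in ("sample_id", "chrom", "pos", "ref", "alt"):
        col = colmap.get(field)
        if col is None or col not in df.columns:
            raise ValueError(f"missing required column {col or field!r}")

    records = []
    n_dropped = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        ref = str(row[colmap["ref"]]).upper()
        alt = str(row[colmap["alt"]]).upper()
        vtype_col = colmap.get("variant_type")
        vtype = str(row[vtype_col]) if vtype_col and vtype_col in row else None
        if (vtype is not None and vtype != "SNP") or len(ref) != 1 or len(alt) != 1 \
                or ref not in BASES or alt not in BASES or ref == alt:
            n_dropped += 1
            continue
        try:
            pos = int(row[colmap["pos"]]) - 1
        except ValueError:
            raise ValueError(f"line {lineno}: unparseable position {row[colmap['pos']]!r}") from None
        consequence = "other"
        cls_col = colmap.get("classification")
        if cls_col and cls_col in row:
            consequence = _MAF_CONSEQUENCE.get(str(row[cls_col]), "other")
        cons_col = colmap.get("consequence")
        if cons_col and cons_col in row:
            consequence = str(row[cons_col])
        chrom = str(row[colmap["chrom"]])
        if genome is not None:
            base = fetch(genome, chrom, pos, pos + 1)
            if base != ref:
                raise ValueError(f"line {lineno}: ref {ref} != genome base {base} at {chrom}:{pos}")
        gene_col = colmap.get("gene_id")
        records.append(
            MutationRecord(
                sample_id=str(row[colmap["sample_id"]]),
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                consequence=consequence,
                gene_id=str(row[gene_col]) if gene_col and gene_col in row else "",
            )
        )
    if n_dropped:
        logger.info("dropped %d non-SNV records", n_dropped)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of mutation records (the package's working container)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": np.array([r.pos for r in records], dtype=int),
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "consequence": [r.consequence for r in records],
            "gene_id": [r.gene_id for r in records],
        }
    )


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: amino acid (or '*') indexed by codon code c0*16 + c1*4 + c2
_AA64 = np.array(
    [
        ("*" if "".join(c) in _STANDARD_TABLE.stop_codons
         else _STANDARD_TABLE.forward_table["".join(c)])
        for c in itertools.product(BASES, repeat=3)
    ]
)
_CODE_MULT = np.array([16, 4, 1])


class ConsequenceAnnotator:
    """Per-site consequence lookup for a set of non-overlapping transcripts.

    Builds, once, the coding-orientation codon structure of every
    transcript and exposes both a scalar ``consequence`` lookup and flat
    per-site arrays used by the cohort simulator. The reading frame is
    taken as frame 0 at the 5' end of the supplied coding exons; a
    trailing partial codon annotates as ``other``.
    """

    def __init__(self, transcripts, genome):
        self.transcripts = list(transcripts)
        pos_list, chrom_list, ref_code_list, cons_list, tindex_list = [], [], [], [], []
        for t_index, t in enumerate(self.transcripts):
            exons = list(t.coding_exons)
            seqs = [fetch(genome, t.chrom, s, e) for s, e in exons]
            if t.strand == "-":
                exons = exons[::-1]
                seqs = [revcomp(s) for s in seqs[::-1]]
            cds = "".join(seqs)
            n = len(cds)
            codes = np.frombuffer(cds.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.int8) - 1
            for b, i in BASE_INDEX.items():
                lut[ord(b)] = i
            c = lut[codes]
            if (c < 0).any():
                raise ValueError(f"{t.transcript_id}: non-ACGT base in CDS")
            n_codons = n // 3
            cod = c[: n_codons * 3].reshape(n_codons, 3)
            codon_code = cod @ _CODE_MULT
            aa_ref = _AA64[codon_code]
            # consequence code per (cds position, coding alt base):
            # 0 synonymous, 1 non-synonymous, 2 other/identity
            cons = np.full((n, 4), 2, dtype=np.uint8)
            for within in range(3):
                idx = np.arange(n_codons) * 3 + within
                mult = _CODE_MULT[within]
                base_here = cod[:, within]
                for alt in range(4):
                    alt_code = codon_code + (alt - base_here) * mult
                    aa_alt = _AA64[alt_code]
                    val = np.where(aa_alt == aa_ref, 0, 1).astype(np.uint8)
                    val[alt == base_here] = 2
                    cons[idx, alt] = val
            # genome position of each coding-orientation index
            if t.strand == "-":
                g_pos_coding = np.concatenate(
                    [np.arange(e - 1, s - 1, -1) for s, e in exons]
                )
            else:
                g_pos_coding = np.concatenate([np.arange(s, e) for s, e in exons])
            # genome-strand ref code and genome-alt-indexed consequences
            if t.strand == "-":
                ref_g = 3 - c
                cons_g = cons[:, ::-1]  # genome alt a maps to coding alt 3-a
            else:
                ref_g = c
                cons_g = cons
            pos_list.append(g_pos_coding)
            chrom_list.extend([t.chrom] * n)
            ref_code_list.append(ref_g)
            cons_list.append(cons_g)
            tindex_list.append(np.full(n, t_index, dtype=np.int32))

        self.pos = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=int)
        self.chrom = np.array(chrom_list)
        self.ref_code = np.concatenate(ref_code_list) if ref_code_list else np.empty(0, dtype=np.int8)
        self.cons = np.concatenate(cons_list) if cons_list else np.empty((0, 4), dtype=np.uint8)
        self.t_index = np.concatenate(tindex_list) if tindex_list else np.empty(0, dtype=np.int32)
        self._site_of = {
            (c_, int(p)): i for i, (c_, p) in enumerate(zip(self.chrom, self.pos))
        }

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def site_index(self, chrom: str, pos: int):
        return self._site_of.get((chrom, pos))

    def consequence(self, chrom: str, pos: int, alt: str) -> str:
        """Consequence of a genome-strand substitution at one site."""
        i = self.site_index(chrom, pos)
        if i is None:
            return "other"
        return CONSEQUENCES[self.cons[i, BASE_INDEX[alt]]]

    def gene_of_site(self, i: int) -> str:
        return self.transcripts[self.t_index[i]].gene_id


def annotate_consequence(record: MutationRecord, transcript, genome) -> str:
    """Consequence of one record against one transcript.

    Positions outside the transcript's CDS return ``other``; a ref
    allele that contradicts the genome raises.
    """
    base = fetch(genome, record.chrom, record.pos, record.pos + 1)
    if base != record.ref:
        raise ValueError(
            f"ref {record.ref} != genome base {base} at {record.chrom}:{record.pos}"
        )
    annotator = ConsequenceAnnotator([transcript], genome)
    return annotator.consequence(record.chrom, record.pos, record.alt)


def filter_synonymous(records, mode: str = "annotation", transcripts=None, genome=None):
    """Restrict to synonymous SNVs.

    ``annotation`` trusts the consequence field parsed from the input
    (the MAF "Silent" flag); ``recompute`` re-annotates every record
    against the supplied transcripts + genome and keeps synonymous calls
    only.
    """
    if mode == "annotation":
        return [r for r in records if r.consequence == "synonymous"]
    if mode != "recompute":
        raise ValueError(f"unknown mode {mode!r}")
    if transcripts is None or genome is None:
        raise ValueError("recompute mode requires transcripts and genome")
    annotator = ConsequenceAnnotator(transcripts, genome)
    out = []
    for r in records:
        cons = annotator.consequence(r.chrom, r.pos, r.alt)
        if cons == "synonymous":
            out.append(replace(r, consequence="synonymous"))
    return out
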