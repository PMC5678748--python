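"""Small sequence helpers shared across modules.

A "genome" anywhere in this package is either a plain ``dict`` mapping
contig name to an uppercase sequence string, or a :class:`pyfaidx.Fasta`
handle; :func:`fetch` hides the difference.
"""

from __future__ import annotations

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(base: str) -> str:
    return COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def contig_length(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Return genome[chrom][start:end) as an uppercase string.

    Raises KeyError for an unknown contig and ValueError for coordinates
    outside the contig.
    """
    if start < 0 or end < start:
        raise ValueError(f"bad interval {chrom}:{start}-{end}")
    seq = genome[chrom]
    if end > len(seq):
        raise ValueError(f"interval {chrom}:{start}-{end} beyond contig end {len(seq)}")
    if isinstance(seq, str):
        return seq[start:end]
    # pyfaidx FastaRecord
    return str(seq[start:end]).upper()
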