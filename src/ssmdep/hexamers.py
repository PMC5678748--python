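"""Exonic splice enhancer (ESE) hexamer sets and region annotation.

ESEs are 6-mers that promote spliceosomal exon recognition; they cluster
within ~70 bp of exon ends. The control ("non-ESE") set is the subset of
all 4096 hexamers whose minimum Hamming distance to every ESE is at
least ``min_distance`` (default 2, i.e. hexamers with one or fewer
differences from an ESE are discarded). Regions are perfect-match scans
of exon sequence restricted to an end window, merged within a set;
regions claimed by both sets are discarded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from ._seq import BASES, revcomp
from .intervals import GenomicInterval

HEXAMER_LEN = 6


@dataclass(frozen=True)
class HexamerSet:
    members: frozenset
    provenance: str = "custom"

    def __post_init__(self):
        for h in self.members:
            if len(h) != HEXAMER_LEN or any(b not in BASES for b in h):
                raise ValueError(f"bad hexamer {h!r}")

    def __contains__(self, item):
        return item in self.members

    def __len__(self):
        return len(self.members)


def enumerate_hexamers() -> HexamerSet:
    """All 4^6 = 4096 distinct hexamers over {A,C,G,T}."""
    members = frozenset("".join(p) for p in itertools.product(BASES, repeat=HEXAMER_LEN))
    return HexamerSet(members=members, provenance="custom")


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def build_non_ese_set(ese: HexamerSet, min_distance: int = 2) -> HexamerSet:
    """Hexamers at Hamming distance >= ``min_distance`` from every ESE."""
    if not ese.members:
        raise ValueError("ESE set is empty")
    if not 1 <= min_distance <= HEXAMER_LEN:
        raise ValueError(f"min_distance {min_distance} outside [1, {HEXAMER_LEN}]")
    members = ese.members
    keep = []
    for h in enumerate_hexamers().members:
        if all(hamming_distance(h, e) >= min_distance for e in members):
            keep.append(h)
    return HexamerSet(members=frozenset(keep), provenance="non_ese")


def _merge(intervals):
    """Merge overlapping or book-ended (start, end) tuples."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def scan_hexamer_regions(
    exon_sequence: str,
    hexamers: HexamerSet,
    end_window: int = 69,
    role: str = "ese",
    chrom: str = "exon",
):
    """Perfect-match scan of an exon (coding-strand) sequence.

    A match at offset ``s`` is reported iff ``s`` lies within
    ``end_window`` of either exon end (``s < end_window`` or
    ``s >= L - end_window``). Overlapping or adjacent matches of the
    same set are merged into maximal regions. Windows containing ``N``
    never match; any other non-ACGT character is an error.

    Returns exon-relative :class:`GenomicInterval` objects.
    """
    seq = exon_sequence.upper()
    bad = set(seq) - set(BASES) - {"N"}
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    L = len(seq)
    if L < HEXAMER_LEN:
        raise ValueError(f"sequence length {L} < {HEXAMER_LEN}")
    matches = []
    for s in range(L - HEXAMER_LEN + 1):
        if not (s < end_window or s >= L - end_window):
            continue
        window = seq[s : s + HEXAMER_LEN]
        if "N" in window:
            continue
        if window in hexamers:
            matches.append((s, s + HEXAMER_LEN))
    return [
        GenomicInterval(chrom, start, end, "+", role)
        for start, end in _merge(matches)
    ]


def resolve_overlaps(ese_regions, non_ese_regions, symmetric: bool = True):
    """Discard regions claimed by both sets.

    With ``symmetric=True`` (default) any overlapping ESE/non-ESE pair
    is removed from both outputs, avoiding asymmetric contamination of
    the control set; with ``symmetric=False`` only the ESE side is
    dropped.
    """
    drop_ese, drop_non = set(), set()
    for i, ese in enumerate(ese_regions):
        for j, non in enumerate(non_ese_regions):
            if ese.overlaps(non):
                drop_ese.add(i)
                if symmetric:
                    drop_non.add(j)
    kept_ese = [r for i, r in enumerate(ese_regions) if i not in drop_ese]
    kept_non = [r for j, r in enumerate(non_ese_regions) if j not in drop_non]
    return kept_ese, kept_non


def read_hexamer_list(path, provenance: str = "custom") -> HexamerSet:
    """Plain-text hexamer list: one 6-mer per line, '#' comments."""
    members = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip().upper()
            if line:
                members.add(line)
    return HexamerSet(members=frozenset(members), provenance=provenance)


def write_hexamer_list(hexamers: HexamerSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {len(hexamers)} hexamers ({hexamers.provenance})\n")
        for h in sorted(hexamers.members):
            fh.write(h + "\n")


def reverse_complement_set(hexamers: HexamerSet) -> HexamerSet:
    return HexamerSet(
        members=frozenset(revcomp(h) for h in hexamers.members),
        provenance=hexamers.provenance,
    )
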