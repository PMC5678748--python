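import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssmdep.intervals import ExonContext, TranscriptModel

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_transcript(exons, strand="+", chrom="chr1", tid="tx1", gene="gene1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        coding_exons=tuple(exons),
    )


def make_exon(start, end, strand="+", chrom="chr1"):
    """A bare ExonContext at [start, end) (single-exon parent)."""
    t = make_transcript([(start, end)], strand=strand, chrom=chrom)
    return ExonContext(parent=t, ordinal=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
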