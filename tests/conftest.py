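import random

import pytest

from selannot.model import AnnotatedTranscript, GenomicInterval, SecPrediction


def interval(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


@pytest.fixture
def simple_prediction():
    """Single-exon plus-strand prediction, Sec at residue 2 (positions 104-106)."""
    return SecPrediction(
        prediction_id="p1",
        family="GPX",
        chrom="chr1",
        strand="+",
        cds_blocks=[interval(101, 160)],
        sec_protein_index=2,
        protein_seq="MU" + "A" * 18,
    )


@pytest.fixture
def rng():
    return random.Random(20240917)
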