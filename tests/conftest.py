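import numpy as np
import pytest

from splicechrom.annotation import GeneModel, GenomeSequence, GenomicInterval
from splicechrom.coverage import FragmentSet


@pytest.fixture
def toy_genome():
    """Two small chromosomes with known composition."""
    rng = np.random.default_rng(11)
    seqs = {
        "chrA": "".join(rng.choice(list("ACGT"), size=10_000)),
        "chrB": "".join(rng.choice(list("ACGT"), size=4_000)),
    }
    return GenomeSequence(seqs)


@pytest.fixture
def simple_gene():
    """+ strand, 3 exons of 100 bp separated by 200-bp introns on chrA."""
    exons = [
        GenomicInterval("chrA", 1000, 1100, "+"),
        GenomicInterval("chrA", 1300, 1400, "+"),
        GenomicInterval("chrA", 1600, 1700, "+"),
    ]
    return GeneModel(
        gene_id="g1",
        span=GenomicInterval("chrA", 1000, 1700, "+"),
        exons=exons,
    )


@pytest.fixture
def minus_gene():
    exons = [
        GenomicInterval("chrA", 3000, 3150, "-"),
        GenomicInterval("chrA", 3500, 3650, "-"),
    ]
    return GeneModel(
        gene_id="g2",
        span=GenomicInterval("chrA", 3000, 3650, "-"),
        exons=exons,
    )


def random_fragments(rng, chrom: str, chrom_len: int, n: int, max_len: int = 300) -> FragmentSet:
    starts = rng.integers(0, chrom_len - 1, n)
    lens = rng.integers(1, max_len, n)
    ends = np.minimum(starts + lens, chrom_len)
    return FragmentSet({chrom: (starts, ends)})
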