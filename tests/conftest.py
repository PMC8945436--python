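import numpy as np
import pytest

from mirbulge.io import UTRRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_utr(gene_id, sequence, start=0, chrom="chr1", strand="+"):
    return UTRRecord(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        sequence=sequence,
        chrom=chrom,
        start=start,
        end=start + len(sequence),
        strand=strand,
    )


@pytest.fixture
def toy_maf(tmp_path):
    """Hand-written 3-species, 12-column alignment block."""
    text = (
        "##maf version=1\n"
        "a score=0\n"
        "s hg19.chr1 10 12 + 1000 ACGTACGTACGT\n"
        "s mm10.chr5 40 12 + 2000 ACGTACGAACGT\n"
        "s rn6.chr2  7 10 + 1500 AC--ACGTACGT\n"
        "\n"
    )
    path = tmp_path / "toy.maf"
    path.write_text(text)
    return path
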