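import io as stringio
import textwrap

import pytest

from galtase.io import GeneModel


@pytest.fixture
def two_gene_models():
    """A + gene and a - gene on chr1, single exons, disjoint."""
    return [
        GeneModel("gplus", "chr1", "+", ((100, 300),)),
        GeneModel("gminus", "chr1", "-", ((500, 800),)),
    ]


@pytest.fixture
def tiny_gff3():
    text = textwrap.dedent(
        """\
        ##gff-version 3
        chr1\tsrc\tgene\t11\t30\t.\t+\t.\tID=g1
        chr1\tsrc\texon\t11\t20\t.\t+\t.\tID=g1.e1;Parent=g1
        chr1\tsrc\texon\t15\t30\t.\t+\t.\tID=g1.e2;Parent=g1
        chr1\tsrc\tgene\t101\t140\t.\t-\t.\tID=g2
        chr1\tsrc\texon\t101\t140\t.\t-\t.\tID=g2.e1;Parent=g2
        """
    )
    return stringio.StringIO(text)


def make_sam(records, chrom="chr1", length=10_000):
    """Assemble a SAM text from (qname, flag, pos1, mapq, cigar, seq, qual, tags)."""
    lines = [f"@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for qname, flag, pos1, mapq, cigar, seq, qual, *tags in records:
        tag_s = ("\t" + "\t".join(tags[0])) if tags and tags[0] else ""
        lines.append(
            f"{qname}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}{tag_s}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def sam_builder():
    return make_sam
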