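import numpy as np
import pysam
import pytest

from liftkit.chain import ChainIndex, parse_chain
from liftkit.synth import emit_chain, generate_genome_pair


def make_header(contigs: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": l} for n, l in sorted(contigs.items())],
    })


def make_record(header, name="r", contig=None, pos=0, cigar="10M", seq=None,
                mapq=60, flag=0, quals=None, tags=()):
    rec = pysam.AlignedSegment(header=header)
    rec.query_name = name
    rec.flag = flag
    if contig is None:
        rec.is_unmapped = True
    else:
        rec.reference_name = contig
        rec.reference_start = pos
        rec.cigarstring = cigar
        rec.mapping_quality = mapq
    if seq is not None:
        rec.query_sequence = seq
        rec.query_qualities = quals if quals is not None else pysam.qualitystring_to_array("I" * len(seq))
    for tag, val in tags:
        rec.set_tag(tag, val)
    return rec


@pytest.fixture(scope="session")
def genome_pair():
    """Deterministic mid-size genome pair with every edit class present."""
    return generate_genome_pair(60_000, seed=3)


@pytest.fixture(scope="session")
def chain_index(genome_pair):
    return ChainIndex(parse_chain(emit_chain(genome_pair.cmap)))
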