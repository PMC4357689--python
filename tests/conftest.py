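"""Shared fixtures: one synthetic bundle per session plus hand-built helpers."""

from __future__ import annotations

import pysam
import pytest

from riboforge import fixtures as fx
from riboforge import ingest
from riboforge.annotation import GenomeSequence, TranscriptModel, load_annotation


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    return fx.make_bundle(d, n_genes=8, seed=1)


@pytest.fixture(scope="session")
def annotation(bundle):
    return load_annotation(bundle.gtf_path, bundle.genome_path)


@pytest.fixture(scope="session")
def chx_profile(bundle):
    return ingest.build_profile(
        bundle.chx_sam, ingest.MULTIMAP_LEQ_15, ingest.ELONGATING
    )


@pytest.fixture(scope="session")
def chx_unique_profile(bundle):
    return ingest.build_profile(bundle.chx_sam, ingest.UNIQUE_ONLY, ingest.ELONGATING)


@pytest.fixture(scope="session")
def ltm_profile(bundle):
    return ingest.build_profile(
        bundle.ltm_sam, ingest.MULTIMAP_LEQ_15, ingest.INITIATING
    )


def make_transcript(
    tid="t1",
    gene="g1",
    chrom="chr",
    strand="+",
    biotype="protein_coding",
    exons=((1, 100),),
    cds=None,
):
    cds_start, cds_end = cds if cds is not None else (None, None)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        chromosome=chrom,
        strand=strand,
        biotype=biotype,
        exons=[tuple(e) for e in exons],
        cds_start=cds_start,
        cds_end=cds_end,
    )


def make_profile(counts, condition=ingest.ELONGATING, policy=ingest.UNIQUE_ONLY):
    """Profile from {(chrom, strand, pos): count}."""
    p = ingest.PsiteProfile(condition=condition, multimap_policy=policy)
    for (chrom, strand, pos), n in counts.items():
        p.add(chrom, strand, pos, n)
    return p


SAM_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr", "LN": 100000}]}
)


def make_read(
    start0,
    length,
    reverse=False,
    nh=1,
    cigar=None,
    name="r",
    seq=None,
    chrom="chr",
    header=SAM_HEADER,
):
    """Hand-built alignment; start0 is the 0-based leftmost reference position."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = chrom
    a.reference_start = start0
    a.flag = 16 if reverse else 0
    a.mapping_quality = 255
    a.cigartuples = cigar if cigar is not None else [(0, length)]
    a.query_sequence = seq if seq is not None else "A" * length
    a.set_tag("NH", nh)
    return a
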