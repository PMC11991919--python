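import numpy as np
import pandas as pd
import pytest

from emblineage.intervals import AnnotationSet, Gene, GenomicInterval, Transfrag, TranscriptModel
from emblineage.qc import CountMatrix, NormalizedMatrix, log_normalize
from emblineage.synthetic import ExpressionDesign, simulate_counts


def make_transcript(tid, gid, blocks, strand="+", chrom="chr1", biotype="protein_coding"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks)
    return TranscriptModel(tid, gid, exons, biotype=biotype)


def make_refs(*transcripts):
    genes = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, Gene(t.gene_id, t.gene_id, [])).transcripts.append(t)
    return AnnotationSet(genes)


def make_transfrag(tid, blocks, strand="+", chrom="chr1"):
    return Transfrag(tid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks))


@pytest.fixture(scope="session")
def simple_refs():
    """One 3-exon gene on chr1:+ at [100,300) [600,800) [1100,1300)."""
    return make_refs(make_transcript("T1", "G1", [(100, 300), (600, 800), (1100, 1300)]))


@pytest.fixture(scope="session")
def marker_study():
    return simulate_counts(ExpressionDesign.marker_recovery(seed=0))


@pytest.fixture(scope="session")
def qc_study():
    return simulate_counts(ExpressionDesign.qc_default(seed=0))


@pytest.fixture()
def small_norm():
    counts = CountMatrix(
        pd.DataFrame(
            [[4, 0, 2], [0, 3, 1], [2, 2, 2], [0, 0, 5]],
            index=["gA", "gB", "gC", "gD"],
            columns=["c1", "c2", "c3"],
        )
    )
    return log_normalize(counts)
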