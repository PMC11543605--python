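import pytest

from isoeval.annotation import TranscriptModel, build_catalog


def tm(tid, exons, strand="+", chrom="chr1", gene="gene", source=""):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons), source)


@pytest.fixture(scope="session")
def reference_models():
    """Hand-built multi-gene reference covering the classification cases.

    geneA (chr1, +): a 5-exon isoform plus an exon-3-skipping isoform.
    geneB (chr1, +): a separate 3-exon gene downstream.
    geneC (chr2, -): a 3-exon gene on the minus strand.
    geneD (chr1, +): a mono-exon gene.
    geneF (chr3, +): two isoforms with alternative first and last introns,
        so a novel combination of annotated junctions exists.
    """
    return [
        tm("refA.1", [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)], gene="geneA"),
        tm("refA.2", [(100, 200), (300, 400), (700, 800), (900, 1000)], gene="geneA"),
        tm("refB.1", [(5000, 5200), (5400, 5600), (5800, 6000)], gene="geneB"),
        tm("refC.1", [(100, 200), (300, 400), (500, 600)], strand="-", chrom="chr2", gene="geneC"),
        tm("refD.1", [(8000, 9000)], gene="geneD"),
        tm("refF.1", [(0, 100), (200, 300), (400, 500)], chrom="chr3", gene="geneF"),
        tm("refF.2", [(0, 80), (180, 320), (430, 500)], chrom="chr3", gene="geneF"),
    ]


@pytest.fixture(scope="session")
def catalog(reference_models):
    return build_catalog(reference_models)
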