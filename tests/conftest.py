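import pytest

from bzipkit.records import GeneModel, ProteinRecord
from bzipkit.grammar import annotate_bzip_domain


def gene_from_cds_lengths(lengths, strand="+", gene_id="g", chromosome="chr1",
                          cds_start=100, intron_length=100):
    """Build a GeneModel with CDS pieces of the given lengths."""
    ivals = []
    pos = cds_start
    for n in lengths:
        ivals.append((pos, pos + n))
        pos += n + intron_length
    if strand == "-":
        # mirror onto a reverse-strand layout: same lengths, descending order
        total = pos
        ivals = [(total - e, total - s) for s, e in ivals]
    return GeneModel(gene_id, chromosome, strand, list(ivals), list(ivals))


@pytest.fixture
def canonical_protein():
    """A minimal protein satisfying the grammar exactly: Asn at index 2,
    Arg at 10, zipper of three Leu heptads from index 20."""
    seq = "GG" + "N" + "QAQAQAQ" + "R" + "EQAQAQAQA" + "L" + "AAAAAA" + "L" + "AAAAAA" + "L" + "GGGGG"
    return ProteinRecord("canon", seq)


@pytest.fixture
def canonical_annotation(canonical_protein):
    ann = annotate_bzip_domain(canonical_protein)
    assert ann is not None
    return ann
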