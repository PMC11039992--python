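import numpy as np
import pytest

from minorsplice.coevolution import PresenceAbsenceMatrix
from minorsplice.splicing.annotations import IntronAnnotation
from minorsplice.splicing.models import GeneModel


@pytest.fixture
def toy_matrix():
    """5 OGs x 4 species with hand-checkable profiles (og5 all-zero)."""
    values = np.array(
        [
            [1, 0, 1, 0],  # og1 (query in most tests)
            [1, 0, 1, 0],  # og2 duplicate of og1
            [1, 1, 0, 0],  # og3
            [0, 1, 0, 1],  # og4 orthogonal to og1
            [0, 0, 0, 0],  # og5 unrankable
        ]
    )
    return PresenceAbsenceMatrix(
        og_ids=["og1", "og2", "og3", "og4", "og5"],
        species_ids=["spA", "spB", "spC", "spD"],
        values=values,
    )


@pytest.fixture
def toy_gene():
    """One plus-strand gene: 5 exons of 100 bp split by 100 bp introns.

    Layout (0-based half-open):
      exon0 0-100, intron0 100-200, exon1 200-300, intron1 300-400,
      exon2 400-500, intron2 500-600, exon3 600-700, intron3 700-800,
      exon4 800-900.
    """
    return GeneModel(
        gene_id="gA",
        chrom="chr1",
        strand="+",
        exons=((0, 100), (200, 300), (400, 500), (600, 700), (800, 900)),
    )


@pytest.fixture
def toy_u12(toy_gene):
    """The middle intron (intron1, 300-400) of toy_gene is U12-type."""
    return [
        IntronAnnotation(
            chrom="chr1", start=300, end=400, strand="+",
            subtype="GT-AG", sources=frozenset({"db1"}),
        )
    ]


@pytest.fixture
def toy_gene_models(toy_gene):
    """toy_gene plus a U2-only background gene on another locus."""
    background = GeneModel(
        gene_id="gB",
        chrom="chr1",
        strand="+",
        exons=((10_000, 10_100), (10_200, 10_300), (10_400, 10_500)),
    )
    return {"gA": toy_gene, "gB": background}
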