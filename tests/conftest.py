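import pytest

from egtkit.seq_io import CodingGene, ProteinAlignment


@pytest.fixture
def toy_genes():
    g1 = CodingGene(id="g1", taxon="t1", compartment="plastid", group="a", cds="ATGGCTGGA")
    g2 = CodingGene(id="g2", taxon="t2", compartment="nuclear", group="b",
                    cds="ATGGCCGGT", genetic_code_id=1)
    return g1, g2


@pytest.fixture
def toy_alignment(toy_genes):
    return ProteinAlignment(ids=["g1", "g2"], rows=["MAG", "MAG"])
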