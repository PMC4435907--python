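import pytest

import hibtarget as ht


@pytest.fixture(scope="session")
def uniform_bg():
    return ht.BackgroundModel.uniform()


@pytest.fixture(scope="session")
def dr1_pfm():
    return ht.example_pfm()


@pytest.fixture(scope="session")
def dr1_pwm(dr1_pfm, uniform_bg):
    return ht.pfm_to_pwm(dr1_pfm, uniform_bg)


@pytest.fixture()
def three_exon_gene():
    return ht.GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        exons=[(20000, 20400), (21000, 21500), (23000, 23600)],
        cds=[(20100, 20400), (21000, 21500), (23000, 23300)],
        utr5=[(20000, 20100)],
        utr3=[(23300, 23600)],
    )


@pytest.fixture()
def minus_gene():
    return ht.GeneModel(
        gene_id="g2",
        chrom="chr1",
        strand="-",
        exons=[(50000, 50400), (51000, 51600)],
        cds=[(50100, 50400), (51000, 51500)],
        utr5=[(51500, 51600)],
        utr3=[(50000, 50100)],
    )


def random_pfm(rng, width):
    """A random count matrix for oracle tests."""
    counts = rng.integers(1, 60, size=(4, width)).astype(float)
    return ht.PositionFrequencyMatrix(counts)
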