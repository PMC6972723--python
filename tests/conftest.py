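import numpy as np
import pytest

from crl4score import data_io
from crl4score.synthetic_cohort import SyntheticConfig, generate, generate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full in-memory synthetic cohort shared across tests."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def generated_dir(default_config, tmp_path_factory):
    """The same cohort written to disk in every pipeline input format."""
    out = tmp_path_factory.mktemp("cohort")
    paths = generate(default_config, out)
    return paths


@pytest.fixture()
def toy_gene_model():
    """Small plus-strand gene: 3 exons, CDS split across them.

    exon1 = [100,200) with utr5 [100,150); exon2 = [300,400);
    exon3 = [500,650) with utr3 [560,650).  CDS length = 50+100+60 = 210.
    """
    return data_io.GeneModel(
        gene="TOY",
        transcript="TOY-1",
        chrom="chrT",
        strand="+",
        exons=[(100, 200), (300, 400), (500, 650)],
        cds=[(150, 200), (300, 400), (500, 560)],
        utr5=[(100, 150)],
        utr3=[(560, 650)],
        flank=50,
        critical_exons=(3,),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
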