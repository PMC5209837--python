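import pytest

from alecross import simulate as sim


@pytest.fixture(scope="session")
def one_chrom_spec() -> sim.GenomeSpec:
    return sim.GenomeSpec((("c1", 1_000_000),), 0.0, 50)


@pytest.fixture(scope="session")
def two_chrom_spec() -> sim.GenomeSpec:
    return sim.GenomeSpec((("c1", 1_000_000), ("c2", 1_000_000)), 0.0, 50)


@pytest.fixture(scope="session")
def phenotype_model() -> sim.PhenotypeModel:
    return sim.PhenotypeModel()


@pytest.fixture(scope="session")
def yeast_spec() -> sim.GenomeSpec:
    return sim.default_genome_spec()


@pytest.fixture(scope="session")
def yeast_parent(yeast_spec) -> sim.HaploidGenome:
    return sim.HaploidGenome(yeast_spec)
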