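import pytest

from carbuild.examples import five_genome_example, worked_example_cars
from carbuild.phylogeny import partition_of


@pytest.fixture(scope="session")
def five_genomes():
    genomes, tree = five_genome_example()
    return genomes, tree, partition_of(tree)


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_cars()
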