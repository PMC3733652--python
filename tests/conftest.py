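import pytest

from reptag import catalog as catalog_mod
from reptag import pipeline, synthetic


@pytest.fixture(scope="session")
def catalog():
    return catalog_mod.load_catalog()


@pytest.fixture(scope="session")
def syn_genome():
    """Default study-condition genome, seed 1."""
    return synthetic.generate_genome(synthetic.default_genome_spec(1))


@pytest.fixture(scope="session")
def syn_result(syn_genome, catalog):
    return pipeline.run_pipeline(
        syn_genome.genome, catalog, orfs=syn_genome.orfs
    )
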