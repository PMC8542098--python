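import pytest

from gdqs import (
    GeneratorSpec,
    example_point_table,
    gen_master_db,
    load_taxonomy,
)


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def master_db(taxonomy):
    return gen_master_db(GeneratorSpec(seed=1), taxonomy)


@pytest.fixture(scope="session")
def point_table(taxonomy):
    return example_point_table(taxonomy)
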