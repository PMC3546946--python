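import pytest

from mitocomp import io as mio
from mitocomp import simulate as sim


@pytest.fixture(scope="session")
def published_tables():
    return {sp: mio.load_published_feature_table(sp)
            for sp in mio.PUBLISHED_SPECIES}


@pytest.fixture(scope="session")
def published_read_stats():
    return mio.load_published_read_stats()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One annotated synthetic mitogenome (genome, table), fixed seed."""
    return sim.generate_annotated_genome(sim.default_layout(seed=1))
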