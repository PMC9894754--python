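import numpy as np
import pytest

from spacerlink import CommunityConfig, generate_community, run_pipeline


@pytest.fixture(scope="session")
def community7():
    """Default synthetic community, seed 7, no spacer mutations."""
    return generate_community(CommunityConfig(seed=7))


@pytest.fixture(scope="session")
def result7(community7):
    """Full pipeline run on the seed-7 community."""
    return run_pipeline(community7.hosts, community7.mge_pool,
                        community7.offtarget_hosts, community7.markers)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
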