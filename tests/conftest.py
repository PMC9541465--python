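import pytest

import mrnm


@pytest.fixture(scope="session")
def small_genotypes():
    return mrnm.simulate_genotypes(120, 200, maf_range=(0.05, 0.5), seed=11)


@pytest.fixture(scope="session")
def small_grm(small_genotypes):
    return mrnm.compute_grm(small_genotypes)
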