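import numpy as np
import pytest

from ph4h3.synthetic_data import SimulationConfig, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study: 8 species, 400 bp root promoter."""
    return generate(SimulationConfig(n_species=8, root_length=400, seed=2))


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    from ph4h3.synthetic_data import write_bundle

    d = tmp_path_factory.mktemp("bundle")
    write_bundle(small_bundle, d)
    return d


def random_dna(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))
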