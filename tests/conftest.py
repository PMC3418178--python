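import numpy as np
import pytest

from barkit.cassette import CassetteSpec, assemble_cassette, generate_barcode
from barkit.mapping import DEFAULT_AD_PRIMERS
from barkit.simulate import ToyGenomeSpec, make_toy_genome


@pytest.fixture(scope="session")
def spec() -> CassetteSpec:
    return CassetteSpec()


@pytest.fixture(scope="session")
def cassette(spec):
    return assemble_cassette(
        spec, generate_barcode(spec.template, 1), 7, extra_forbidden=DEFAULT_AD_PRIMERS
    )


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(ToyGenomeSpec(rng_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_bases(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
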