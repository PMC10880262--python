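import numpy as np
import pytest

from satarch.simulate import demo_library


@pytest.fixture(scope="session")
def library():
    return demo_library()


@pytest.fixture(scope="session")
def motif(library):
    return library.motif


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), n)).decode()
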