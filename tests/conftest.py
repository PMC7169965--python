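import numpy as np
import pytest

from prionscope.params import ScoreParams
from prionscope.synthetic import FamilySpec, generate_family


@pytest.fixture(scope="session")
def params() -> ScoreParams:
    return ScoreParams.default()


@pytest.fixture(scope="session")
def small_family():
    """Ten default-condition sequences with ground truth."""
    spec = FamilySpec(n_sequences=10, seed=42)
    return generate_family(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_protein(rng: np.random.Generator, length: int) -> str:
    from prionscope.params import AA20

    return "".join(rng.choice(list(AA20), size=length))
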