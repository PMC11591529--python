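import numpy as np
import pytest

from mrseg.synthetic import SyntheticParams, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cases(targets, seed0, canvas=(64, 64)):
    """Deterministic synthetic cases for training/eval fixtures."""
    return [
        generate_case(SyntheticParams(target_rf=t, seed=seed0 + i, canvas=canvas))
        for i, t in enumerate(targets)
    ]


@pytest.fixture(scope="session")
def train_cases():
    """16 cases spanning all grades, 64x64."""
    targets = [10, 20, 25, 35, 40, 45, 55, 60, 70, 15, 38, 65, 22, 42, 62, 30.5]
    return make_cases(targets, seed0=100)


@pytest.fixture(scope="session")
def holdout_cases():
    """8 held-out cases, distinct seeds, 64x64."""
    return make_cases([12, 35, 58, 20, 44, 66, 28, 52], seed0=900)
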