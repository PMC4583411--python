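import numpy as np
import pytest

from gazevalence.synthetic import SyntheticConfig, generate

NEUTRAL_SHIFT = {c: 0.0 for c in ("unpleasant", "neutral", "pleasant")}
UNIT_MULT = {c: 1.0 for c in ("unpleasant", "neutral", "pleasant")}


@pytest.fixture(scope="session")
def small_recordset():
    """A small strong-effect synthetic dataset: 10 images, 4 observers."""
    cfg = SyntheticConfig(
        n_unpleasant=3, n_neutral=4, n_pleasant=3, n_observers=4, seed=7
    )
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
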