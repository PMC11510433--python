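import numpy as np
import pytest

from dessol.sigma_profiles import GRID_SIZE, SigmaProfile, SolventComposition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_profile(values, compound_id="X", temperature=298.15):
    return SigmaProfile(compound_id, temperature, np.asarray(values, dtype=float))


@pytest.fixture
def random_profile(rng):
    def _make(compound_id="X", temperature=298.15):
        return make_profile(rng.normal(size=GRID_SIZE), compound_id, temperature)

    return _make


@pytest.fixture
def constant_profile():
    def _make(c, compound_id="X", temperature=298.15):
        return make_profile(np.full(GRID_SIZE, float(c)), compound_id, temperature)

    return _make


@pytest.fixture
def binary_composition():
    return SolventComposition([("A", 0.25), ("B", 0.75)])
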