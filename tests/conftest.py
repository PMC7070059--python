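import numpy as np
import pytest

from gutperm.pk import Dose, PKParameters
from gutperm.synthetic import MOUSE_FIXED


@pytest.fixture
def mouse_fixed() -> dict:
    return dict(MOUSE_FIXED)


@pytest.fixture
def oral_dose() -> Dose:
    return Dose.from_mg_per_kg(2.0)  # 40,000 ng in a 20 g mouse


@pytest.fixture
def sampling_times() -> np.ndarray:
    return np.array([0.5, 1, 2, 4, 6, 8, 10, 12, 16, 24, 36, 48], float)


def random_params(rng: np.random.Generator, bimodal: bool = False) -> PKParameters:
    """A random valid parameter set spanning a few orders of magnitude."""
    kw = dict(
        ka=10 ** rng.uniform(-5, 0),
        kce=10 ** rng.uniform(-3, 0),
        k10=10 ** rng.uniform(-2, 0.5),
        k12=10 ** rng.uniform(-2, 0.5),
        k21=10 ** rng.uniform(-2, 0.5),
        Vc=10 ** rng.uniform(-0.5, 1),
    )
    if bimodal:
        kw |= dict(ka2=10 ** rng.uniform(-5, 0), lag2=rng.uniform(0.5, 12))
    return PKParameters(**kw)
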