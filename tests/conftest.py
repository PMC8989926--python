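import warnings

import numpy as np
import pytest

from uslesion import PhantomConfig, PipelineConfig, generate_phantom

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def lesion_phantom():
    """One deterministic phantom with a mid-size lesion."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def normal_phantom():
    """One deterministic lesion-free phantom."""
    return generate_phantom(PhantomConfig(lesion_center=None, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_box(rng: np.random.Generator, frame: int = 64,
               min_side: int = 2) -> "BBox":
    from uslesion import BBox

    w = int(rng.integers(min_side, frame // 2))
    h = int(rng.integers(min_side, frame // 2))
    x = int(rng.integers(0, frame - w))
    y = int(rng.integers(0, frame - h))
    return BBox(float(x), float(y), float(w), float(h))
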