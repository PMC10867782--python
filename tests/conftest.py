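import numpy as np
import pytest

from tsegan.generator import NetworkConfig, TranslationGenerator
from tsegan.phantom import PhantomConfig, generate_phantom_pair


@pytest.fixture(scope="session")
def tiny_cfg() -> NetworkConfig:
    """Smallest legal architecture: 32-pixel frames, 16-pixel ROI."""
    return NetworkConfig(base_channels=4, roi_size=16, global_size=32, seed=0)


@pytest.fixture(scope="session")
def tiny_generator(tiny_cfg) -> TranslationGenerator:
    return TranslationGenerator(tiny_cfg)


@pytest.fixture(scope="session")
def phantom_sample():
    return generate_phantom_pair(PhantomConfig(seed=11, target_score=3))


@pytest.fixture(scope="session")
def small_phantoms():
    """Eight 96-px phantoms, scores cycling 1..5."""
    return [generate_phantom_pair(PhantomConfig(
        image_size=96, nodule_radius_range=(10, 24), seed=i,
        target_score=1 + i % 5)) for i in range(8)]
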