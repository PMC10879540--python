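import numpy as np
import pytest

from ercpnet import (NetworkConfig, SyntheticSpec, build_network,
                     generate_synthetic_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_net():
    """Small default-variant network: stem width 4, 32x32 inputs, 3 classes."""
    return build_network(NetworkConfig(variant="ercp_net", stem_width=4,
                                       num_classes=3, input_size=32, seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 3-class synthetic set, 12 images per class at 32x32."""
    return generate_synthetic_dataset(
        SyntheticSpec(num_classes=3, per_class=12, image_size=32, seed=9))


def zero_parameters(module):
    """Set every learnable parameter of a module tree to zero."""
    for p in module.parameters():
        p.data[...] = 0.0
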