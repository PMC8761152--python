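import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from memqa.synthetic_data import BundleSpec, generate_bundle, synthetic_reference_library


@pytest.fixture(scope="session")
def bundle30():
    """Noise-free 4-helix bundle with 30 A hydrophobic thickness."""
    return generate_bundle(BundleSpec(target_thickness=30.0, helix_length=24, seed=0))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Same geometry with 0.5 A coordinate noise."""
    return generate_bundle(
        BundleSpec(target_thickness=30.0, helix_length=24, noise_sigma=0.5, seed=1)
    )


@pytest.fixture(scope="session")
def reference_library():
    """The eight synthetic stand-in reference folds."""
    return synthetic_reference_library(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
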