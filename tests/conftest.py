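import numpy as np
import pytest

import histofuse as hf


@pytest.fixture(scope="session")
def small_features():
    """Separable 3-class table: 5 informative, 3 redundant, 10 noise dims."""
    return hf.gen_features(
        hf.SyntheticFeatureSpec(
            n_per_class=30,
            n_classes=3,
            d_informative=5,
            d_redundant=3,
            d_noise=10,
            class_sep=3.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def tiny_images():
    """30 synthetic H&E-like tiles at side 64, 3 classes."""
    return hf.gen_images(
        hf.SyntheticImageSpec(n_per_class=10, side=64, seed=7, images_per_patient=2)
    )
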