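import numpy as np
import pytest

from lesionfuse.synthetic_data import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """70-sample equal-class cohort with signal in both modalities."""
    cfg = SynthConfig(n_samples=70, class_proportions=tuple([1 / 7] * 7),
                      image_size=32, signal_mode="both", seed=42,
                      missing_age_rate=0.1)
    manifest, images = generate_cohort(cfg)
    return cfg, manifest, images
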