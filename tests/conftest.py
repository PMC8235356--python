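import numpy as np
import pytest

from ventasync import synth
from ventasync.preprocess import record_to_images


@pytest.fixture(scope="session")
def settings():
    return synth.VentilatorSettings()


@pytest.fixture(scope="session")
def small_record():
    """Noisy mixed-class record shared by read-only tests."""
    return synth.generate_dataset({"DT": 5, "IEE": 10, "OTHER": 20},
                                  noise_sd=0.02, seed=42)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free record for separability / oracle checks."""
    return synth.generate_dataset({"DT": 8, "IEE": 12, "OTHER": 20},
                                  noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def small_images(small_record):
    return record_to_images(small_record)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
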