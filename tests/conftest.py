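import numpy as np
import pytest

from signglove import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_profile():
    return sd.SubjectProfile(
        noise_accel=0.0, noise_gyro=0.0, noise_flex=0.0, seed=7
    )


@pytest.fixture(scope="session")
def small_dynamic_dataset():
    """3 subjects x 4 dynamic gestures x 3 trials (36 recordings)."""
    return sd.make_dataset(3, sd.dynamic_templates(), seed=42, n_trials=3)


@pytest.fixture(scope="session")
def small_static_dataset():
    """3 subjects x 4 static gestures x 3 trials (36 recordings)."""
    return sd.make_dataset(3, sd.static_templates(), seed=43, n_trials=3)
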