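import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import strokesym as ss

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """120 noisy samples with the default (reported) class mix."""
    samples, manifest = ss.generate_cohort(ss.CohortConfig(n_samples=120, seed=42))
    return samples, manifest


@pytest.fixture(scope="session")
def clean_sample():
    """One noise-free forehand drive with shoulder + trunk asymmetry."""
    return ss.generate_stroke(
        ss.default_template("forehand_drive"),
        ss.AsymmetryParams(shoulder_rot_asym=22.0, spine_flexion=12.0),
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
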