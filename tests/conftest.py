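import numpy as np
import pytest

from sfeptr.synthetic import SyntheticIonSpec, SyntheticRunConfig, make_structure_fixture


@pytest.fixture
def single_sample_config():
    """One well-populated sample ion, 60 s run."""
    return SyntheticRunConfig(
        duration=60.0,
        ions=(
            SyntheticIonSpec(
                mz_true=303.233,
                kind="sample",
                amplitude=10_000.0,
                elution_center=30.0,
                elution_width_sigma=5.0,
            ),
        ),
        seed=42,
    )


@pytest.fixture
def mixed_config():
    """Sample + background + lockmass ions in one short run."""
    return SyntheticRunConfig(
        duration=120.0,
        ions=(
            SyntheticIonSpec(303.233, "sample", amplitude=8000.0, elution_center=60.0, elution_width_sigma=6.0),
            SyntheticIonSpec(282.279, "sample", amplitude=5000.0, elution_center=70.0, elution_width_sigma=8.0),
            SyntheticIonSpec(199.150, "background", background_level=8.0, decay_onset=30.0, decay_rate=0.03),
            SyntheticIonSpec(255.233, "background", background_level=5.0, decay_onset=30.0, decay_rate=0.02),
            SyntheticIonSpec(322.048, "lockmass", background_level=30.0, decay_onset=30.0, decay_rate=0.01),
        ),
        polarity="positive",
        seed=7,
    )


@pytest.fixture(scope="session")
def fixture_sdf():
    return make_structure_fixture(15, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
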