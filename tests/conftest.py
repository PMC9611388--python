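import numpy as np
import pytest

from eegconn.montage import generate_montage
from eegconn.synth import CouplingSpec, ErpSpec, PowerModSpec, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def montage():
    return generate_montage("paper64")


@pytest.fixture(scope="session")
def small_config():
    """One short session with every effect type injected."""
    return SynthConfig(
        sessions=("s",),
        n_trials_per_condition=5,
        coupling_specs=(
            CouplingSpec(target_channels=("C3",), band_center=5.5,
                         concentration=4.0, window=(0.15, 0.40)),
        ),
        power_specs=(
            PowerModSpec(channels=("C5", "CP3", "CP5"), band=(8.0, 13.0),
                         gain=0.5, window=(0.30, 0.70)),
        ),
        erp_specs=(
            ErpSpec(channels=("PO7", "PO8"), latency=0.25, width=0.03,
                    amplitude={"PO7": 2.0, "PO8": 6.0}),
        ),
        blink_rate=6.0,
        outlier_trial_fraction=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_recording(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Artifact-free background-only recording (no injected effects)."""
    return SynthConfig(sessions=("s",), n_trials_per_condition=5,
                       blink_rate=0.0, outlier_trial_fraction=0.0, seed=21)


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return generate_recording(clean_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
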