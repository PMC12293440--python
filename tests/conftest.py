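import numpy as np
import pytest

from erpgraph import EpochSet, Montage
from erpgraph.synth import (
    CouplingGroup,
    GeneratorSpec,
    generate_epochs,
)


@pytest.fixture
def small_montage():
    return Montage(["F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(small_montage):
    """20 trials x 8 channels x 300 samples at 250 Hz with a planted
    delta-band coupling contrast between the two conditions."""
    spec = GeneratorSpec(
        n_trials_per_condition=10,
        montage=small_montage,
        coupling=(
            CouplingGroup(channels=("F3", "Fz", "F4"), band=(1.0, 4.0),
                          kappa={"A": 0.9, "B": 0.1}),
        ),
        seed=77,
    )
    return generate_epochs(spec)


@pytest.fixture
def noise_epochs(small_montage):
    """Coupling-free two-condition epochs (pure background)."""
    spec = GeneratorSpec(
        n_trials_per_condition=6, montage=small_montage, seed=99
    )
    return generate_epochs(spec)


def make_epochs(data, fs=250.0, t0=-200.0, labels=None, channels=None):
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, _ = data.shape
    if labels is None:
        labels = np.array(["A", "B"] * (n_trials // 2 + 1))[:n_trials]
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    return EpochSet(data=data, fs=fs, t0=t0, labels=labels,
                    montage=Montage(channels))
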