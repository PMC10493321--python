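import numpy as np
import pytest

import tfpf


def two_class_specs(n_channels=8, fs=160.0, duration=4.0, noise_sd=1.0,
                    kappa=1000.0, weight=0.5):
    """Two simulation specs with strong coupling on disjoint channel pairs:
    class 0 couples (0, 1), class 1 couples (2, 3)."""
    common = dict(n_channels=n_channels, fs=fs, duration=duration, noise_sd=noise_sd)
    spec_a = tfpf.SimulationSpec(
        coupled_pairs=((0, 1, 12.0, kappa, weight),), **common)
    spec_b = tfpf.SimulationSpec(
        coupled_pairs=((2, 3, 12.0, kappa, weight),), **common)
    return spec_a, spec_b


@pytest.fixture(scope="session")
def separable_samples():
    """CNN samples for the strongly separable two-class dataset
    (30 trials/class, 8 channels, 4-s trials)."""
    spec_a, spec_b = two_class_specs()
    trials = tfpf.make_labeled_dataset(spec_a, spec_b, 30, seed=7)
    return tfpf.trials_to_input_sets(trials)


@pytest.fixture(scope="session")
def small_learnable():
    """A small, quickly learnable sample set (10 trials/class) for training
    sanity checks."""
    spec_a, spec_b = two_class_specs()
    trials = tfpf.make_labeled_dataset(spec_a, spec_b, 10, seed=11)
    samples = tfpf.trials_to_input_sets(trials)
    X = np.stack([s.values for s in samples])
    y = np.asarray([int(s.label) for s in samples])
    return samples, X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
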