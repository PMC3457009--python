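import numpy as np
import pytest

from casum.slice_model import (
    CellGroupModel,
    NeuronModel,
    SliceConfig,
    SliceModel,
    build_slice,
    run_experiment,
)


@pytest.fixture(scope="session")
def toy_neuron():
    """Single neuron: w=(1,0), T=0.5, amplitude 0.1."""
    return NeuronModel(weights=(1.0, 0.0), threshold=0.5, amplitude=0.1)


@pytest.fixture(scope="session")
def graded_slice():
    """Threshold-free (graded) linear groups: output = pattern @ effective weights.

    Three groups of 2-3 neurons with identity transforms and T = 0, so
    every analysis step has an exact closed-form expectation.
    """
    rng = np.random.default_rng(12345)
    groups = []
    for gi, size in enumerate([2, 3, 2]):
        neurons = tuple(
            NeuronModel(
                weights=tuple(rng.uniform(0.1, 1.0, size=5)),
                threshold=0.0,
                amplitude=float(rng.uniform(0.02, 0.05)),
            )
            for _ in range(size)
        )
        groups.append(CellGroupModel(group_id=f"lin{gi}", neurons=neurons))
    return SliceModel(n_electrodes=5, groups=tuple(groups), inhibition_offset=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def default_slice():
    return build_slice(SliceConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_matrix(default_slice):
    import dataclasses

    slc = dataclasses.replace(default_slice, noise_sd=0.0)
    return run_experiment(slc, trials=1, seed=0)


@pytest.fixture(scope="session")
def noisy_matrix(default_slice):
    return run_experiment(default_slice, trials=3, seed=11)
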