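import dataclasses

import numpy as np
import pytest

from dacue.synth import SynthParams, default_kernels, generate_session


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def small_params() -> SynthParams:
    """A quick-to-generate session: 20 + 20 trials, one neuron."""
    return dataclasses.replace(SynthParams(), n_trials_pre=20, n_trials_inact=20)


@pytest.fixture(scope="session")
def session_default(default_params):
    return generate_session(default_params, 1234)


@pytest.fixture(scope="session")
def session_small(small_params):
    return generate_session(small_params, 99)


def null_value_params(**overrides) -> SynthParams:
    """Generator with CS value coding removed (LR and SR amplitudes equal)."""
    kernels = list(default_kernels())
    kernels[1] = dataclasses.replace(kernels[1],
                                     amplitude_sr=kernels[1].amplitude_lr)
    base = dict(kernels=tuple(kernels), n_trials_inact=0)
    base.update(overrides)
    return dataclasses.replace(SynthParams(), **base)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
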