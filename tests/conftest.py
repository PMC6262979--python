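"""Shared fixtures: one desk-scale simulated dataset reused across detector tests."""

import numpy as np
import pytest

import assemblybench as ab


@pytest.fixture(scope="session")
def desk_dataset():
    """217-neuron, 1800 s surrogate recording with 10 embedded assemblies.

    Simulated once per session; every detector's end-to-end test runs on it.
    """
    array = ab.build_hex_array(8)
    gen = ab.GeneratorParams(centre_radius=6.0)
    params = ab.SimulationParams(T=1800.0)
    config = ab.sample_configuration(array, gen, 10)
    dff, extras = ab.simulate_dataset(config, params, 20)
    return {
        "array": array,
        "config": config,
        "params": params,
        "dff": dff,
        "extras": extras,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
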