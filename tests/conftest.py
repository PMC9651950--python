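"""Shared fixtures.

The expensive fixtures (a full-size phantom and its workflow-2 run) are
session-scoped: several test modules and the acceptance tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

import synconn as sc

#: fixed seed for every randomized fixture in the suite
SEED = 20


@pytest.fixture(scope="session")
def default_cfg() -> sc.PipelineConfig:
    return sc.PipelineConfig()


@pytest.fixture(scope="session")
def small_phantom() -> sc.PhantomDataset:
    """Quick 128-cube phantom for unit-level checks."""
    spec = sc.PhantomSpec(volume_shape=(128, 128, 128), n_neurons=2,
                          n_presyn_per_neuron=8, n_postsyn_apposed=4,
                          tube_step_count=80, rng_seed=SEED)
    return sc.generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom() -> sc.PhantomDataset:
    """Full default study conditions: 256-cube, 3 neurons, 40 presynaptic sites
    each, 15 apposed postsynaptic pairs, noise-free."""
    return sc.generate_phantom(sc.PhantomSpec(rng_seed=SEED))


@pytest.fixture(scope="session")
def neuron1_mask(default_phantom, default_cfg) -> sc.BinaryMask:
    return sc.postprocess_neuron_mask(default_phantom.neuron_channels[0], default_cfg)


@pytest.fixture(scope="session")
def w2_channels(default_phantom, neuron1_mask) -> dict:
    return {
        "presyn": default_phantom.presyn_channel,
        "postsyn": default_phantom.postsyn_channel,
        "neuron1_mask": neuron1_mask,
    }


@pytest.fixture(scope="session")
def w2_report(w2_channels, default_cfg) -> sc.WorkflowReport:
    return sc.run_workflow(2, w2_channels, default_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
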