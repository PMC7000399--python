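"""Shared fixtures: small simulated datasets reused across analysis tests.

The main fixture keeps the full population structure (all five populations
represented, default gains and behavior) at a reduced neuron count so the
full analysis chain runs in seconds.
"""

import numpy as np
import pytest

from numcrow import selectivity
from numcrow.synthdata import SimConfig, build_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_seq_sample=10,
        n_sim_sample=10,
        n_delay_num=12,
        n_format_only=4,
        n_nonsel=8,
        trials_per_condition=16,
    )


@pytest.fixture(scope="session")
def dataset(small_config):
    return build_dataset(small_config, seed=11)


@pytest.fixture(scope="session")
def sel_table(dataset):
    return selectivity.classify_all(dataset)


@pytest.fixture(scope="session")
def delay_ids(sel_table):
    ids = selectivity.delay_selective_ids(sel_table)
    assert ids, "fixture dataset must yield delay-selective neurons"
    return ids


@pytest.fixture(scope="session")
def ablation_dataset():
    """Format-dependent populations only: no format-independent delay code."""
    cfg = SimConfig(
        n_seq_sample=8,
        n_sim_sample=8,
        n_delay_num=0,
        n_format_only=6,
        n_nonsel=2,
        trials_per_condition=16,
    )
    return build_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def clean_error_dataset():
    """Error trials are behavioral only; spikes always follow the true sample."""
    cfg = SimConfig(
        n_seq_sample=0,
        n_sim_sample=0,
        n_delay_num=10,
        n_format_only=2,
        n_nonsel=2,
        trials_per_condition=16,
        error_corruption=False,
    )
    return build_dataset(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
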