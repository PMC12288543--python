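import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from plastcov.core import CoverageProfile
from plastcov.simulate import SimConfig, simulate_coverage, simulate_plastome

SMALL_PARTITIONS = {"LSC": 6000, "IRb": 2000, "SSC": 1500, "IRa": 2000}


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(partition_lengths=dict(SMALL_PARTITIONS),
                     n_sc_genes=12, n_ir_genes=3, gene_length_mean=300)


@pytest.fixture
def small_record(small_config):
    record, truth = simulate_plastome(small_config, seed=101, sample_id="S1")
    return record


@pytest.fixture
def small_profile(small_config, small_record):
    profile, truth = simulate_coverage(small_record, small_config, seed=202)
    return profile


@pytest.fixture
def flat_profile(small_record):
    return CoverageProfile("S1", np.full(len(small_record), 10, dtype=np.int64))
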