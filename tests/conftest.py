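import pytest

from circamir import pipeline
from circamir.synthetic_data import (SimulationConfig, make_reference,
                                     simulate_reads)


@pytest.fixture(scope="session")
def small_config():
    # desk-scale study conditions: 4 libraries, moderate depth
    return SimulationConfig(seed=3, depth_per_library=30_000, n_conserved=12,
                            n_novel_true=4, n_novel_decoy=4)


@pytest.fixture(scope="session")
def reference(small_config):
    return make_reference(small_config)


@pytest.fixture(scope="session")
def sim_reads(reference, small_config):
    return simulate_reads(reference, small_config)


@pytest.fixture(scope="session")
def processed(small_config):
    ref, results, true_counts = pipeline.run_synthetic(small_config)
    return ref, results, true_counts
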