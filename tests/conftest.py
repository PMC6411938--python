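import numpy as np
import pytest

from pitrimseq.pipeline import RunConfig, run_pipeline
from pitrimseq.synthetic_data import (
    SimulationConfig,
    build_references,
    simulate_library,
)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down experiment for unit tests (structure, not statistics)."""
    return SimulationConfig(
        seed=7,
        n_clusters=2,
        cluster_length=6000,
        n_loci_per_cluster=20,
        n_reads=5000,
    )


@pytest.fixture(scope="session")
def small_refs(small_config):
    return build_references(small_config)


@pytest.fixture(scope="session")
def wt_small(small_config, small_refs):
    return simulate_library(small_config, small_refs, "WT")


@pytest.fixture(scope="session")
def mutant_small(small_config, small_refs):
    return simulate_library(small_config, small_refs, "mutant")


@pytest.fixture(scope="session")
def study_run():
    """One full-depth matched WT/mutant run under the default study conditions."""
    return run_pipeline(RunConfig(simulation=SimulationConfig(seed=424)))
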