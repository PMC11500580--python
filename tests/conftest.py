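import numpy as np
import pytest

from tespectra.synthetic_data import SimulationConfig, simulate_experiment

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated experiment shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=6,
        gene_length_range=(600, 900),
        samples_per_condition=1,
        replicates=2,
        coverage=25.0,
        gap_bp=600,
    )
    return simulate_experiment(cfg, want_reads=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
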