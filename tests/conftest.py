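import math

import pytest

from asediverge import SimulationConfig, simulate_dataset


CONSERVED_ONLY = {
    "conserved": 1.0,
    "all_cis": 0.0,
    "all_trans": 0.0,
    "cis_plus_trans": 0.0,
    "cis_times_trans": 0.0,
    "compensatory": 0.0,
}


@pytest.fixture(scope="session")
def null_dataset():
    """Global-null simulation: no cis, trans, or misexpression effects."""
    config = SimulationConfig(
        n_genes=600,
        seed=101,
        category_fractions=dict(CONSERVED_ONLY),
        misexpression_fraction=0.0,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def effect_dataset():
    """Mixed-category simulation with strong effects and deep counts."""
    config = SimulationConfig(
        n_genes=1200,
        seed=202,
        effect_size_log2=2.0,
        baseline_log2_mean=math.log2(500),
        misexpression_fraction=0.0,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def read_dataset():
    """Small read-level simulation with diagnostic sites and alignments."""
    config = SimulationConfig(
        n_genes=30,
        n_replicates=2,
        reads_per_gene=60,
        error_rate=0.0,
        seed=303,
    )
    return simulate_dataset(config, with_reads=True)
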