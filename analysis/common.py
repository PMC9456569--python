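"""Shared configuration of the synthetic benchmark analyses.

The benchmark emulates the real study design: two parental species (R, S)
and their F1 hybrid, three replicate antennal libraries per group, allele-
level counts for the hybrid, mean depth 500 per gene, NB dispersion 0.05,
and strong regulatory effects (2 log2 units) for the non-conserved half of
the genes.
"""

from pathlib import Path

from asediverge import SimulationConfig, TestConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1

BENCHMARK = SimulationConfig(
    n_genes=2000,
    n_replicates=3,
    effect_size_log2=2.0,
    misexpression_fraction=0.1,
    misexpression_shift_log2=1.0,
    seed=SEED,
)

TESTING = TestConfig(alpha=0.05, min_mean_count=10.0)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
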