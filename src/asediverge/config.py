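"""Configuration objects for simulation, testing, and pipeline runs.

All stochastic behaviour is controlled by a single integer seed carried on
:class:`SimulationConfig`; every downstream random draw derives from it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Regulatory divergence categories a gene's (cis, trans) effect pair can imply.
REGULATORY_CATEGORIES = (
    "conserved",
    "all_cis",
    "all_trans",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
)

#: Inheritance modes of hybrid total expression relative to the parents.
INHERITANCE_MODES = (
    "conserved",
    "additive",
    "RR_dominant",
    "SS_dominant",
    "overdominant",
    "underdominant",
    "ambiguous",
    "uninformative",
)

#: Sample group labels used throughout the package. R and S name the two
#: parental species (mnemonic: reference and second species).
GROUPS = (
    "parent_R",
    "parent_S",
    "hybrid_total",
    "hybrid_allele_R",
    "hybrid_allele_S",
)


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _default_fractions() -> dict[str, float]:
    return {
        "conserved": 0.50,
        "all_cis": 0.125,
        "all_trans": 0.125,
        "cis_plus_trans": 0.10,
        "cis_times_trans": 0.05,
        "compensatory": 0.10,
    }


@dataclass
class SimulationConfig:
    """Parameters of the two-species + F1-hybrid generative model.

    Parameters
    ----------
    n_genes
        Number of genes to simulate.
    n_replicates
        Replicate libraries per sample group (both parents and the hybrid).
    baseline_log2_mean, baseline_log2_sd
        Log-normal baseline expression: ``log2(mu_g) ~ N(mean, sd)``. The
        default centres genes at a mean count of 500 per library.
    category_fractions
        Proportions of genes drawn from each true regulatory category
        (must sum to 1).
    effect_size_log2
        Magnitude of the cis effect ``c`` and trans effect ``t`` (log2
        units) where a category makes them nonzero. Signs are random
        unless the category constrains them.
    misexpression_fraction, misexpression_shift_log2
        Fraction of genes carrying a hybrid-specific multiplicative shift
        ``m`` (log2 units, random sign) on the hybrid total.
    dispersion
        Global negative-binomial dispersion alpha (variance =
        mean + alpha * mean**2); 0 degenerates to Poisson.
    library_size_factors
        Optional per-sample scaling of expected means; default all 1.
    assignment_rate
        Probability that a hybrid read can be assigned to a parental
        allele (the remainder is "unassigned"). The default leaves ~45%
        unassigned, which is in the range reported for real moth F1
        transcriptomes.
    transcript_length, read_length, snp_per_kb, error_rate, reads_per_gene
        Read-level simulation: transcript template length, read length,
        density of species-diagnostic sites, probability of a sequencing
        error at a covered diagnostic base, and hybrid reads drawn per
        gene per replicate.
    seed
        Integer seed fixing all downstream randomness.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    baseline_log2_mean: float = math.log2(500.0)
    baseline_log2_sd: float = 1.0
    category_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_size_log2: float = 1.0
    misexpression_fraction: float = 0.1
    misexpression_shift_log2: float = 1.0
    dispersion: float = 0.05
    library_size_factors: list[float] | None = None
    assignment_rate: float = 0.55
    transcript_length: int = 500
    read_length: int = 150
    snp_per_kb: float = 10.0
    error_rate: float = 0.005
    reads_per_gene: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("n_genes and n_replicates must be positive")
        unknown = set(self.category_fractions) - set(REGULATORY_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown regulatory categories: {sorted(unknown)}")
        total = sum(self.category_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"category_fractions sum to {total!r}, expected 1")
        if any(v < 0 for v in self.category_fractions.values()):
            raise ConfigurationError("category_fractions must be non-negative")
        if self.baseline_log2_sd < 0:
            raise ConfigurationError("baseline_log2_sd must be >= 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        for name in ("misexpression_fraction", "assignment_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.snp_per_kb < 0:
            raise ConfigurationError("snp_per_kb must be >= 0")
        if self.read_length <= 0 or self.transcript_length <= 0:
            raise ConfigurationError("read_length and transcript_length must be positive")
        if self.read_length >= self.transcript_length:
            raise ConfigurationError("read_length must be smaller than transcript_length")
        if self.library_size_factors is not None and any(
            f <= 0 for f in self.library_size_factors
        ):
            raise ConfigurationError("library_size_factors must be positive")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TestConfig:
    """Settings of the differential-testing and classification stages.

    ``alpha`` is applied to BH-adjusted p-values by default
    (``use_adjusted=False`` switches the classifier to raw p-values).
    ``min_mean_count`` is the informativeness gate: a gene must reach this
    mean normalized count in every group entering one of its contrasts.
    ``dispersion_shrink`` interpolates per-gene moment dispersions toward
    the across-gene trend on the log scale (1 = fully pooled).
    ``interaction_sign_rule`` selects how a gene significant in all three
    regulatory tests is split into cis+trans vs cis×trans: by agreement of
    the parental and allelic ratio signs ("parental_vs_allelic", default)
    or of the allelic and ratio-difference signs ("allelic_vs_trans").
    """

    alpha: float = 0.05
    min_mean_count: float = 10.0
    dispersion_floor: float = 1e-4
    dispersion_shrink: float = 1.0
    dispersion_mode: str = "per_group"
    pseudocount: float = 0.5
    use_adjusted: bool = True
    interaction_sign_rule: str = "parental_vs_allelic"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_mean_count < 0:
            raise ConfigurationError("min_mean_count must be >= 0")
        if not 0.0 <= self.dispersion_shrink <= 1.0:
            raise ConfigurationError("dispersion_shrink must be in [0, 1]")
        if self.dispersion_floor <= 0:
            raise ConfigurationError("dispersion_floor must be > 0")
        if self.dispersion_mode not in ("per_group", "pooled"):
            raise ConfigurationError("dispersion_mode must be 'per_group' or 'pooled'")
        if self.interaction_sign_rule not in ("parental_vs_allelic", "allelic_vs_trans"):
            raise ConfigurationError(
                "interaction_sign_rule must be 'parental_vs_allelic' or 'allelic_vs_trans'"
            )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "TestConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown TestConfig keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    """Top-level pipeline run: stage toggles, paths, and nested configs."""

    output_dir: str = "asediverge_run"
    seed: int = 0
    simulate_reads: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    testing: TestConfig = field(default_factory=TestConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # propagate the run seed into the simulation stage
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        data = dict(data)
        sim = data.pop("simulation", {})
        tst = data.pop("testing", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation", "testing"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(
            simulation=SimulationConfig.from_mapping(sim),
            testing=TestConfig.from_mapping(tst),
            **data,
        )

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "simulate_reads": self.simulate_reads,
            "simulation": self.simulation.to_dict(),
            "testing": self.testing.to_dict(),
            "log_level": self.log_level,
        }

    def config_hash_payload(self) -> str:
        # output_dir is excluded: the hash identifies the analysis, not
        # where its artifacts happen to live
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return json.dumps(payload, sort_keys=True)
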