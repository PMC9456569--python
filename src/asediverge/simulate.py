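"""Generative model for two parental species and their F1 hybrid.

The model is parameterized per gene by a baseline expression ``mu``, a cis
effect ``c`` (allele-specific, log2), a trans effect ``t`` (shared, log2)
and a hybrid-specific misexpression shift ``m`` (log2). Expected means:

* ``parent_R = mu * 2**(+(c+t)/2)``
* ``parent_S = mu * 2**(-(c+t)/2)``
* ``hybrid_total = 2**m * (parent_R + parent_S) / 2``
* ``hybrid_allele_R = (hybrid_total/2) * 2**(+c/2)``
* ``hybrid_allele_S = (hybrid_total/2) * 2**(-c/2)``

so the parental log2 ratio is exactly ``c + t`` and the hybrid allelic
log2 ratio is exactly ``c``: cis variants act allele-specifically while
trans variants shift both alleles together. ``mu`` is the geometric
mid-parent. Counts are negative-binomial around size-factor-scaled means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GROUPS, REGULATORY_CATEGORIES, ConfigurationError, SimulationConfig
from .matrix import CountMatrix

_EXPECTED_GROUPS = GROUPS


@dataclass
class GeneTruth:
    """Simulated ground truth for one gene."""

    gene_id: str
    mu: float
    c: float  # cis effect, log2
    t: float  # trans effect, log2
    m: float  # hybrid misexpression shift, log2
    true_regulatory_category: str
    true_inheritance_mode: str


@dataclass
class ReadRecord:
    """One simulated hybrid read with its hidden parental origin."""

    read_id: str
    sample: str
    gene_id: str
    start: int  # 0-based leftmost position on the transcript
    sequence: str
    true_origin: str  # "R" or "S"


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    truth: list[GeneTruth]
    reads: list[ReadRecord] | None = None
    sites: pd.DataFrame | None = None  # gene, pos (1-based), allele_R, allele_S
    transcripts: dict[str, str] = field(default_factory=dict)  # gene -> R-haplotype sequence

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [g.gene_id for g in self.truth],
                "mu": [g.mu for g in self.truth],
                "c": [g.c for g in self.truth],
                "t": [g.t for g in self.truth],
                "m": [g.m for g in self.truth],
                "true_regulatory_category": [g.true_regulatory_category for g in self.truth],
                "true_inheritance_mode": [g.true_inheritance_mode for g in self.truth],
            }
        ).set_index("gene")


def category_from_effects(c: float, t: float) -> str:
    """Regulatory category implied by a (cis, trans) effect pair.

    Opposite-sign effects that cancel exactly are compensatory; any other
    opposite-sign pair is cis x trans. The generator only emits cis x trans
    pairs whose trans effect dominates (|t| > |c|), since otherwise the net
    parental and allelic divergences share a sign and an outcome-based
    classifier has no way to see the opposition.
    """
    if c == 0 and t == 0:
        return "conserved"
    if t == 0:
        return "all_cis"
    if c == 0:
        return "all_trans"
    if math.copysign(1, c) == math.copysign(1, t):
        return "cis_plus_trans"
    if t == -c:
        return "compensatory"
    return "cis_times_trans"


def expected_means(truth: GeneTruth, group: str) -> float:
    """Expected expression of one gene in one sample group (counts scale)."""
    if group not in _EXPECTED_GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    pr = truth.mu * 2.0 ** (+(truth.c + truth.t) / 2.0)
    ps = truth.mu * 2.0 ** (-(truth.c + truth.t) / 2.0)
    if group == "parent_R":
        return pr
    if group == "parent_S":
        return ps
    mu_f = 2.0**truth.m * (pr + ps) / 2.0
    if group == "hybrid_total":
        return mu_f
    if group == "hybrid_allele_R":
        return (mu_f / 2.0) * 2.0 ** (+truth.c / 2.0)
    return (mu_f / 2.0) * 2.0 ** (-truth.c / 2.0)


def _inheritance_from_means(pr: float, ps: float, mu_f: float, rel_tol: float = 1e-9) -> str:
    """Inheritance mode implied by exact expected means (no noise)."""

    def close(a: float, b: float) -> bool:
        return math.isclose(a, b, rel_tol=rel_tol)

    parents_equal = close(pr, ps)
    if parents_equal and close(mu_f, pr):
        return "conserved"
    if mu_f > max(pr, ps) and not (close(mu_f, pr) or close(mu_f, ps)):
        return "overdominant"
    if mu_f < min(pr, ps) and not (close(mu_f, pr) or close(mu_f, ps)):
        return "underdominant"
    if not parents_equal:
        if close(mu_f, pr):
            return "RR_dominant"
        if close(mu_f, ps):
            return "SS_dominant"
        return "additive"
    return "ambiguous"


def simulate_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[GeneTruth]:
    """Draw per-gene baselines, effects, and their implied true categories.

    Effect construction per category (e = ``effect_size_log2``, s a random
    sign): conserved c=t=0; all_cis c=se; all_trans t=se; cis_plus_trans
    c=t=se (same sign); compensatory c=se, t=-se (exact cancellation);
    cis_times_trans c=se, t=-2se (opposition with trans dominating, so the
    parental and allelic ratios genuinely disagree in direction).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cats = [c for c in REGULATORY_CATEGORIES if config.category_fractions.get(c, 0) > 0]
    probs = np.array([config.category_fractions[c] for c in cats])
    probs = probs / probs.sum()
    n = config.n_genes
    drawn = rng.choice(len(cats), size=n, p=probs)
    log2_mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    mis = rng.random(size=n) < config.misexpression_fraction
    mis_signs = rng.choice([-1.0, 1.0], size=n)

    e = config.effect_size_log2
    truths: list[GeneTruth] = []
    width = len(str(n - 1))
    for i in range(n):
        cat = cats[drawn[i]]
        s = signs[i]
        if cat == "conserved":
            c, t = 0.0, 0.0
        elif cat == "all_cis":
            c, t = s * e, 0.0
        elif cat == "all_trans":
            c, t = 0.0, s * e
        elif cat == "cis_plus_trans":
            c, t = s * e, s * e
        elif cat == "compensatory":
            c, t = s * e, -s * e
        else:  # cis_times_trans
            c, t = s * e, -2.0 * s * e
        m = float(mis_signs[i] * config.misexpression_shift_log2) if mis[i] else 0.0
        mu = float(2.0**log2_mu[i])
        g = GeneTruth(
            gene_id=f"g{i:0{width}d}",
            mu=mu,
            c=float(c),
            t=float(t),
            m=m,
            true_regulatory_category=cat,
            true_inheritance_mode="",
        )
        pr = expected_means(g, "parent_R")
        ps = expected_means(g, "parent_S")
        mu_f = expected_means(g, "hybrid_total")
        g.true_inheritance_mode = _inheritance_from_means(pr, ps, mu_f)
        truths.append(g)
    return truths


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + alpha*mean**2."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise RuntimeError("negative expected mean: internal error in the generative model")
    if alpha == 0.0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for rep in range(1, config.n_replicates + 1):
        rows.append((f"RR_{rep}", "parent_R", rep))
    for rep in range(1, config.n_replicates + 1):
        rows.append((f"SS_{rep}", "parent_S", rep))
    for rep in range(1, config.n_replicates + 1):
        rows.append((f"F1_{rep}", "hybrid_total", rep))
        rows.append((f"F1_{rep}.R", "hybrid_allele_R", rep))
        rows.append((f"F1_{rep}.S", "hybrid_allele_S", rep))
    return pd.DataFrame(rows, columns=["sample", "group", "replicate"]).set_index("sample")


def sample_counts(
    truth: list[GeneTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Draw the count matrix: parents (totals) and hybrid (total + alleles).

    A hybrid library is generated as three independent NB components —
    R-assignable, S-assignable (splitting ``assignment_rate`` of the total
    mean with odds ``2**c``) and unassigned — whose sum is stored as the
    hybrid total, so R + S + unassigned = total holds exactly while every
    stored count is itself a negative-binomial draw with dispersion
    ``alpha``. (Thinning a single total draw instead would leave the two
    allele counts of a library correlated through their shared total and
    make the allelic ratio less variable across replicates than an NB
    sample; real allele-level counts carry their own assignment and
    mapping variability.) The summed hybrid total is consequently less
    overdispersed than a one-shot NB draw of the same mean — the price of
    exact read-count conservation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    samples = _sample_table(config)
    if config.library_size_factors is not None:
        if len(config.library_size_factors) != len(samples):
            raise ConfigurationError(
                f"library_size_factors has {len(config.library_size_factors)} entries, "
                f"need {len(samples)} (one per sample)"
            )
        sf = pd.Series(np.asarray(config.library_size_factors, float), index=samples.index)
    else:
        sf = pd.Series(1.0, index=samples.index)

    genes = [g.gene_id for g in truth]
    c_arr = np.array([g.c for g in truth])
    mean_by_group = {
        grp: np.array([expected_means(g, grp) for g in truth]) for grp in GROUPS
    }
    p_r = 2.0 ** (c_arr / 2.0) / (2.0 ** (c_arr / 2.0) + 2.0 ** (-c_arr / 2.0))

    data: dict[str, np.ndarray] = {}
    alpha = config.dispersion
    for rep in range(1, config.n_replicates + 1):
        data[f"RR_{rep}"] = _nb_draw(rng, mean_by_group["parent_R"] * sf[f"RR_{rep}"], alpha)
    for rep in range(1, config.n_replicates + 1):
        data[f"SS_{rep}"] = _nb_draw(rng, mean_by_group["parent_S"] * sf[f"SS_{rep}"], alpha)
    mu_f = mean_by_group["hybrid_total"]
    rate = config.assignment_rate
    for rep in range(1, config.n_replicates + 1):
        sfac = sf[f"F1_{rep}"]
        r_counts = _nb_draw(rng, mu_f * rate * p_r * sfac, alpha)
        s_counts = _nb_draw(rng, mu_f * rate * (1.0 - p_r) * sfac, alpha)
        unassigned = _nb_draw(rng, mu_f * (1.0 - rate) * sfac, alpha)
        data[f"F1_{rep}"] = r_counts + s_counts + unassigned
        data[f"F1_{rep}.R"] = r_counts
        data[f"F1_{rep}.S"] = s_counts

    frame = pd.DataFrame(data, index=pd.Index(genes, name="gene"), dtype=np.int64)
    frame = frame[list(samples.index)]
    return SimulatedDataset(counts=CountMatrix(frame, samples), truth=truth)


_BASES = np.array(list("ACGT"))


def simulate_reads(
    truth: list[GeneTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Simulate hybrid reads carrying species-diagnostic alleles.

    Per gene a random transcript template (the R haplotype, which also
    serves as the mapping reference) receives ``round(L * snp_per_kb /
    1000)`` diagnostic sites at distinct random positions; the S haplotype
    differs at exactly those sites. Reads start uniformly along the
    transcript, come from the R or S haplotype with odds ``2**c``, and the
    base at each covered diagnostic site is replaced by a uniformly chosen
    different base with probability ``error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    length = config.transcript_length
    n_sites = int(round(length * config.snp_per_kb / 1000.0))
    if n_sites > length:
        raise ConfigurationError("snp_per_kb implies more sites than transcript bases")

    reads: list[ReadRecord] = []
    site_rows: list[tuple[str, int, str, str]] = []
    transcripts: dict[str, str] = {}
    serials: dict[str, int] = {}

    for g in truth:
        template = rng.choice(_BASES, size=length)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) if n_sites else np.array([], dtype=int)
        hap_r = template.copy()
        hap_s = template.copy()
        for pos in positions:
            ref = hap_r[pos]
            alt = rng.choice(_BASES[_BASES != ref])
            hap_s[pos] = alt
            site_rows.append((g.gene_id, int(pos) + 1, str(ref), str(alt)))
        transcripts[g.gene_id] = "".join(hap_r)

        p_r = 2.0 ** (g.c / 2.0) / (2.0 ** (g.c / 2.0) + 2.0 ** (-g.c / 2.0))
        for rep in range(1, config.n_replicates + 1):
            sample = f"F1_{rep}"
            origins = np.where(rng.random(config.reads_per_gene) < p_r, "R", "S")
            starts = rng.integers(0, length - config.read_length + 1, size=config.reads_per_gene)
            for origin, start in zip(origins, starts):
                hap = hap_r if origin == "R" else hap_s
                seq = hap[start : start + config.read_length].copy()
                if config.error_rate > 0:
                    covered = positions[(positions >= start) & (positions < start + config.read_length)]
                    for pos in covered:
                        if rng.random() < config.error_rate:
                            cur = seq[pos - start]
                            seq[pos - start] = rng.choice(_BASES[_BASES != cur])
                serial = serials.get(sample, 0)
                serials[sample] = serial + 1
                reads.append(
                    ReadRecord(
                        read_id=f"{sample}:{serial:07d}",
                        sample=sample,
                        gene_id=g.gene_id,
                        start=int(start),
                        sequence="".join(seq),
                        true_origin=str(origin),
                    )
                )

    sites = pd.DataFrame(site_rows, columns=["gene", "pos", "allele_R", "allele_S"])
    sites = sites.sort_values(["gene", "pos"]).reset_index(drop=True)
    counts = sample_counts(truth, config, rng)
    return SimulatedDataset(
        counts=counts.counts,
        truth=truth,
        reads=reads,
        sites=sites,
        transcripts=transcripts,
    )


def simulate_dataset(config: SimulationConfig, with_reads: bool = False) -> SimulatedDataset:
    """One-call generator: truth plus counts (and optionally reads)."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    if with_reads:
        return simulate_reads(truth, config, rng)
    return sample_counts(truth, config, rng)
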