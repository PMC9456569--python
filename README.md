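# asediverge

Allele-specific expression (ASE) analysis of interspecific F1-hybrid
RNA-seq designs: assign hybrid reads to parental origin via
species-diagnostic SNPs, test the standard expression contrasts with a
negative-binomial Wald test, classify genes into inheritance modes and
*cis*/*trans* regulatory patterns, and quantify expression-divergence
magnitude by regulatory category.

## The science

Two related species R and S differ in expression of many genes. In an
F1 hybrid both parental alleles share one *trans* environment, so three
comparisons decompose the divergence:

| quantity | contrast | measures |
|---|---|---|
| `L_P` | parent R vs parent S | cis + trans divergence |
| `L_H` | R allele vs S allele in the hybrid | cis divergence only |
| `L_T = L_P − L_H` | ratio difference | trans divergence |

Significance of the three tests classifies each gene as conserved, all
*cis*, all *trans*, *cis* + *trans*, *cis* × *trans*, compensatory, or
ambiguous; comparing the hybrid's total expression with each parent
(`L_FR`, `L_FS`) classifies inheritance (conserved, additive,
dominant, over-/underdominant), with over-/underdominance — hybrid
expression outside the parental range — defined as misexpression.
Expression-divergence magnitude is `|L_P|` per gene, compared across
regulatory categories with Wilcoxon rank-sum tests.

Because real datasets of this design are rarely deposited, the package
ships a first-class synthetic-data module: a generative model with
per-gene baseline, cis effect `c`, trans effect `t` and misexpression
shift `m` (so `E[L_P] = c + t`, `E[L_H] = c` exactly), NB counts with
exact read-count conservation for the hybrid, and read-level simulation
of transcripts carrying diagnostic SNPs with sequencing errors. Every
downstream stage is validated by recovering this known truth; see
`docs/methods.md` for the model and its limits.

## Worked example

The numbered scripts under `analysis/` run the full synthetic benchmark
(2000 genes, 3 replicates per group, mean depth 500, effects of 2 log2
units, 10% misexpression) and write tables under `results/`:

```
cd analysis
python 01_simulate.py && python 02_assign_reads.py && python 03_test_contrasts.py
python 04_classify.py && python 05_divergence_stats.py
```

`04_classify.py` prints the classification of the benchmark:

```
regulatory-pattern proportions:
conserved          0.4765
all_cis            0.1240
all_trans          0.1190
cis_plus_trans     0.1095
compensatory       0.1035
cis_times_trans    0.0475
ambiguous          0.0200
misexpression proportion (over+under / informative): 0.0605
non-conserved true-category recovery: 0.9860
```

98.6% of genes simulated with a non-conserved regulatory category are
assigned their true category; the inferred proportions track the
simulated mixture (50% conserved, 12.5/12.5/10/5/10% for the effect
categories). `05_divergence_stats.py` then shows the expected
divergence ordering — median `|log2(R/S)|` of 3.96 for *cis* + *trans*
genes (same-sign effects add), ~2.0 for all *cis* and all *trans*, and
0.17 for compensatory genes (cis and trans cancel) — and a VST + PCA
diagnostic in which PC1 separates the two parental groups with the
hybrid total at the mid-point and the two hybrid allele sets flanking
it.

The same pipeline is available as a CLI
(`asediverge simulate|assign|test|classify|stats|demo`); `asediverge
demo --seed 1 --out run/` reproduces the whole chain with a manifest of
artifact checksums, byte-identical across reruns of the same seed.

As a library:

```python
from asediverge import SimulationConfig, simulate_dataset, run_standard_contrasts, classify_dataset

dataset = simulate_dataset(SimulationConfig(n_genes=2000, seed=1))
contrasts = run_standard_contrasts(dataset.counts)   # P, H, T, FR, FS
classes = classify_dataset(contrasts)                # per-gene modes + patterns
```

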