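# Methods

## The question and the design

When two related species differ in how much of a gene they express, the
difference can come from *cis*-regulatory changes (linked to the allele
they regulate) or *trans*-regulatory changes (diffusible factors acting
on both alleles). An F1 hybrid puts both parental alleles in one shared
*trans* environment, so:

- the **parental contrast** `L_P = log2(R/S)` between the two species
  measures the combined effect of cis and trans divergence,
- the **allelic contrast** `L_H = log2(R-allele / S-allele)` inside the
  hybrid isolates the cis component (both alleles see the same trans
  factors), and
- the **difference** `L_T = L_P − L_H` isolates the trans component.

Comparing the hybrid's total expression with each parent (`L_FR`,
`L_FS`) classifies the inheritance mode, with expression outside the
parental range (over-/underdominance) defined as misexpression.

The measured allele-level counts come from assigning hybrid RNA-seq
reads to a parental origin via species-diagnostic sites — positions at
which each species is fixed for a different base.

## Generative model

Each gene g has baseline `mu_g` (log2-normal across genes), cis effect
`c_g`, trans effect `t_g`, and hybrid-specific misexpression shift
`m_g`, all in log2 units. Expected means:

```
parent_R        = mu * 2^(+(c+t)/2)
parent_S        = mu * 2^(−(c+t)/2)
hybrid_total    = 2^m * (parent_R + parent_S) / 2
hybrid_allele_R = (hybrid_total/2) * 2^(+c/2)
hybrid_allele_S = (hybrid_total/2) * 2^(−c/2)
```

The symmetric ±/2 split makes `mu` a geometric mid-parent and gives
exactly `E[L_P] = c + t` and `E[L_H] = c`. Misexpression is a
multiplicative shift on the hybrid total only — the minimal mechanism
that produces over/underdominant calls.

True categories follow from the effect pair: conserved (c = t = 0), all
cis (t = 0), all trans (c = 0), cis + trans (same sign), compensatory
(t = −c exactly), cis × trans (opposite signs without full
cancellation). For cis × trans the generator draws `c = ±e, t = ∓2e`:
with `|t| = |c|` the pair would be compensatory by definition, and with
`|t| < |c|` the parental and allelic ratios share a sign, so an
outcome-based classifier has no way to observe the opposition. The
trans-dominant choice is the minimal one that keeps `|c|` at the
configured magnitude and makes the category recoverable.

### Counts

Counts are negative binomial with variance `mean + α·mean²` (global
`α = 0.05` by default, `α = 0` degenerating to Poisson), scaled by
optional per-library size factors. A hybrid library is generated as
three *independent* NB components — R-assignable, S-assignable
(splitting `assignment_rate = 0.55` of the total mean with odds `2^c`)
and unassigned — whose sum is stored as the hybrid total. This keeps
the conservation identity `R + S + unassigned = total` exact per gene
per library while every stored count is itself an NB draw. Two
consequences worth knowing:

- thinning a single total draw instead would leave the two allele
  counts of a library positively correlated through the shared total,
  making the allelic ratio across replicates much less variable than an
  NB model implies (a test modelling them as independent NB samples
  would then be severely conservative);
- the summed hybrid total has variance `mean + α·Σ share_i²·mean²`
  (≈ `mean + 0.354·α·mean²` at the defaults), i.e. it is tighter than a
  one-shot NB library draw. The per-group dispersion estimation below
  absorbs this.

The ~45% unassigned fraction matches the assignment rates reported for
real interspecific moth hybrids.

### Reads

Per gene, a random transcript template (the R haplotype, also the
mapping reference) of 500 bp receives `round(L·snp_per_kb/1000)`
diagnostic sites (default 10/kb) at distinct random positions; the S
haplotype differs exactly there. Reads (150 bp) start uniformly, come
from the R or S haplotype with odds `2^c`, and the base at each covered
diagnostic site is replaced by a uniformly chosen different base with
probability `error_rate`. With one covered site, an error sends a read
to the other parent with probability `e/3` (one of the three wrong
bases) and to "uninformative" with `2e/3` — the package's measured
misassignment rates reproduce this.

## Read assignment

Diagnostic sites are the intersection of the two species' consensus
tables: both fixed for a single A/C/G/T base, bases differing;
heterozygous, multiallelic or missing sites are excluded. Coordinates
are 1-based externally (VCF), 0-based half-open internally. A read is
assigned by the diagnostic bases it covers: unanimous informative
support → that parent; support for both parents → conflict ("from two
parents"); no covered site, or only bases matching neither allele →
uninformative ("unknown"). Bases matching neither allele (sequencing
errors) never veto an otherwise unanimous read. Conflict and
uninformative reads are excluded from allele counts but retained in
totals, keeping the partition identity testable. Base quality is
ignored by default (threshold configurable upstream of this package's
scope).

## Differential testing

Normalization is median-of-ratios: `factor_j = median_g counts[g,j] /
geomean_g`, over genes positive in every sample. Hybrid allele columns
are treated as separate samples; their size factors absorb depth and
the unassigned fraction. The documented limitation is that
within-library pairing of the two allele columns is ignored — with the
generative model above the columns are independent, and for real data
this choice mirrors the standard count-framework treatment.

The test is an NB Wald test on `L = log2(m̂_A/m̂_B)` of mean normalized
counts: `Var(m̂) = (1/n²)·Σ_s (m/sf_s + α m²)` propagated to the log2
scale, two-sided normal p on `L/se`. A pseudocount of 0.5 is added to
both group means only when one is zero, preserving the exact
A/B-swap symmetry. Genes below a mean normalized count of 10 in either
group are uninformative and excluded from testing and BH adjustment
(Benjamini–Hochberg per contrast family, α = 0.05 on adjusted p-values
by default; raw p is available behind a switch since published
classifications do not always state which was used).

Dispersion: per-gene method-of-moments `(s² − m̄)/m̄²` on normalized
counts, floored at 1e-4, shrunk (fully, by default) toward an
across-gene trend. Two numerical choices matter:

- the trend is the ratio-of-sums `Σ_g(s² − m̄) / Σ_g(m̄² − s²/n)`, not a
  mean or median of per-gene ratios: at replicate-level degrees of
  freedom the per-gene ratio's numerator and denominator are correlated
  and the ratio is biased low (the median more so), which in turn
  inflates every Wald statistic; the `−s²/n` term makes `m̄²` unbiased
  for the squared true mean;
- dispersion is estimated **per sample group** by default
  (`dispersion_mode="per_group"`), because group dispersions genuinely
  differ here (see the hybrid-total variance above); each contrast uses
  the dispersions of the two groups it compares. A single pooled
  estimate (the `"pooled"` mode) is available but miscalibrates each
  contrast in a different direction when groups differ.

With these choices the raw-p rejection rate under the global null is
~0.05 for all five contrasts at 3 replicates (measured by the
acceptance suite), without any resampling machinery.

The trans test is `L_T = L_P − L_H`, `se_T = √(se_P² + se_H²)`, normal
two-sided — valid because the parental and allelic contrasts use
disjoint libraries.

## Classification

Regulatory pattern from (sig_P, sig_H, sig_T): FFF conserved, TTF all
cis, TFT all trans, FTT compensatory, TTT split by sign agreement of
`L_P` and `L_H` into cis + trans (agree) vs cis × trans (oppose); the
remaining combinations are ambiguous, as is a significant contrast with
an exact-zero L (possible only under contrived input). The alternative
split convention (sign of `L_H` vs `L_T`) is available behind
`interaction_sign_rule`. Inheritance from (sig_P, sig_FR, sig_FS) with
the signs of `L_FR`, `L_FS`: all-null conserved; hybrid significantly
above (below) both parents overdominant (underdominant), with no
requirement on sig_P — a hybrid can exceed two equal parents; between
two diverged parents and different from both, additive (requires
sig_P); tracking one parent while differing from the other, dominant
toward the tracked parent; everything else ambiguous. Any gene
uninformative in a required contrast is uninformative. Both tables are
total and mutually exclusive; the test suite proves agreement with an
independent enumeration oracle over every flag/sign/informativeness
combination.

## Divergence statistics

Expression-divergence magnitude is `|L_P|` per informative gene, joined
with the inferred regulatory category. Category comparisons record
Shapiro–Wilk normality per category (magnitudes of count ratios are
rarely normal; the rank test is computed regardless) and run two-sided
Wilcoxon rank-sum tests on all category pairs with ≥ 3 genes, BH
across pairs. Under equal effect magnitudes the expected ordering is
cis + trans > all cis ≈ all trans > compensatory ≈ conserved, because
same-sign effects add in `L_P` and compensatory effects cancel.

The VST is the documented simple `log2(normalized + 1)` — deterministic
and adequate for sample-level diagnostics — not a fitted
mean–variance transformation. PCA takes the top 500 most-variable genes
(configurable), centers genes, and uses an SVD with a deterministic
sign convention (largest-magnitude loading positive); variance
explained is relative to the selected centered matrix. Expression–
phenotype association is Spearman with average-rank ties; for fewer
than 10 groups the p-value is the exact permutation null (all orderings
enumerated), asymptotic otherwise.

## Problem sizes and defaults

The benchmark analyses use 2000 genes, 3 replicates/group, mean depth
500, dispersion 0.05, effects of 2 log2 units where nonzero, BH 0.05 —
sizes at which every acceptance property is measurable in seconds.
Estimator-consistency checks use depth 1000 with 6 replicates;
read-level checks use ~10⁵ reads over 100 genes. Category fractions
default to 50% conserved, 12.5% all cis, 12.5% all trans, 10%
cis + trans, 5% cis × trans, 10% compensatory — the rough rank order
seen in published hybrid ASE studies (conserved most common,
interaction categories least).

## What the simulation does and does not show

The generator produces clean, balanced designs: no mapping bias toward
the reference species, no GC or length effects, no outlier libraries,
no correlation between effect size and expression level, interchangeable
group labels (no sex chromosomes or reciprocal-cross asymmetries), and
diagnostic sites with uniform density and error rates. Passing tests
therefore demonstrate that the statistical machinery is correct and
calibrated under its stated model — not that real hybrid data meet that
model. In particular, reference-mapping bias in real data shifts
allelic ratios toward the reference species systematically; the
package's assignment-bias summary (exact binomial per gene against 0.5)
is the diagnostic for that, not a correction.

## Known limitations

- Power for the allelic contrast is bounded by the assigned fraction:
  at 55% assignment each allele column carries ~27% of the hybrid
  library.
- The Wald test is slightly anticonservative in the extreme low-count
  regime; the informativeness gate (mean ≥ 10) is the guard.
- Category recovery saturates near depth 500 at the default dispersion
  (the NB term, not counting noise, dominates the standard error), so
  deeper sequencing stops improving classification.
- No covariate GLM, no fold-change shrinkage, no outlier replacement,
  no indel-aware site handling, no quantitative "% cis" partitioning.
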