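"""Simulate the benchmark: two parents + F1 hybrid with known truth.

Writes the gene-by-sample count table (parents as totals; hybrid as total
plus R/S allele columns), the sample design, and the per-gene truth table
(baseline mu, cis effect c, trans effect t, misexpression shift m, true
categories) under results/benchmark/.
"""

from asediverge import io as aio
from asediverge.simulate import simulate_dataset

from common import BENCHMARK, outdir


def main() -> None:
    out = outdir("benchmark")
    dataset = simulate_dataset(BENCHMARK)
    aio.write_counts(dataset.counts, out / "counts.tsv")
    aio.write_design(dataset.counts.samples, out / "design.tsv")
    aio.write_truth(dataset, out / "truth.tsv")

    truth = dataset.truth_frame()
    print(f"simulated {len(truth)} genes x {dataset.counts.data.shape[1]} samples (seed {BENCHMARK.seed})")
    print("true regulatory categories:")
    print(truth.true_regulatory_category.value_counts().to_string())
    print("true inheritance modes:")
    print(truth.true_inheritance_mode.value_counts().to_string())
    print(f"wrote counts/design/truth to {out}")


if __name__ == "__main__":
    main()
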