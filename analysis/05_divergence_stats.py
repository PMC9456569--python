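"""Divergence magnitude by regulatory category, plus sample diagnostics.

Computes |log2(R/S)| per informative gene, compares its distribution
across inferred regulatory categories with Shapiro-Wilk-gated Wilcoxon
rank-sum tests, and runs the VST + PCA sample diagnostic. The expected
qualitative ordering: same-direction cis + trans changes diverge most,
single-mechanism (all cis / all trans) changes less, and compensatory
changes (cis and trans cancelling) least.
"""

import importlib

from asediverge import io as aio
from asediverge.stats import compare_categories, divergence_magnitude, run_pca, vst_transform
from asediverge.testing import estimate_size_factors

from common import RESULTS, outdir

load_contrasts = importlib.import_module("04_classify").load_contrasts


def main() -> None:
    out = outdir("divergence")
    contrasts = load_contrasts(RESULTS / "contrasts")
    classifications = aio.read_table(RESULTS / "classification" / "classification.tsv")
    divergence = divergence_magnitude(contrasts.P, classifications)
    aio.write_table(divergence, out / "divergence.tsv")
    comparisons = compare_categories(divergence)
    comparisons.to_csv(out / "category_comparisons.tsv", sep="\t", index=False)

    medians = divergence.groupby("regulation").magnitude.median().sort_values(ascending=False)
    print("median |log2(R/S)| by inferred regulatory category:")
    print(medians.round(3).to_string())
    n_sig = int((comparisons.padj < 0.05).sum())
    print(f"{n_sig} of {len(comparisons)} category pairs differ at BH 0.05")

    bench = RESULTS / "benchmark"
    matrix = aio.read_count_matrix(bench / "counts.tsv", bench / "design.tsv")
    sf = estimate_size_factors(matrix)
    pca = run_pca(vst_transform(matrix.data, sf))
    aio.write_table(pca.scores, out / "pca_scores.tsv")
    aio.write_table(pca.loadings, out / "pca_loadings.tsv")
    print("variance explained by the first three components:",
          [round(float(v), 3) for v in pca.variance_explained[:3]])
    print("PC1 scores by sample:")
    print(pca.scores["PC1"].round(2).to_string())
    print(f"wrote divergence artifacts to {out}")


if __name__ == "__main__":
    main()
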