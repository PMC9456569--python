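"""Differential testing: the five contrasts of the hybrid design.

Loads the benchmark counts, normalizes by median-of-ratios, estimates NB
dispersion per sample group, and runs the NB Wald contrasts: parental
divergence (P), hybrid allelic imbalance (H), their difference (T, the
trans component), and hybrid total vs each parent (FR, FS).
"""

from asediverge import io as aio
from asediverge.testing import run_standard_contrasts

from common import RESULTS, TESTING, outdir


def main() -> None:
    bench = RESULTS / "benchmark"
    out = outdir("contrasts")
    matrix = aio.read_count_matrix(bench / "counts.tsv", bench / "design.tsv")
    contrasts = run_standard_contrasts(matrix, TESTING)
    for key, result in contrasts.as_dict().items():
        aio.write_table(result.table, out / f"contrast_{key}.tsv")

    print("size factors:")
    print(contrasts.size_factors.round(3).to_string())
    for key, result in contrasts.as_dict().items():
        table = result.table
        n_inf = int(table.informative.sum())
        n_sig = int((table.padj[table.informative] < TESTING.alpha).sum())
        print(f"contrast {key}: {n_inf} informative genes, {n_sig} significant at BH {TESTING.alpha}")
    print(f"wrote contrast tables to {out}")


if __name__ == "__main__":
    main()
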