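"""Classification: inheritance modes and cis/trans regulatory patterns.

Applies both decision tables to the contrast results, writes the per-gene
classification and category proportions (the synthetic analogue of the
inheritance-mode and regulatory-pattern bar charts), summarizes
misexpression, and scores recovery against the simulated truth.
"""

import json

import pandas as pd

from asediverge import io as aio
from asediverge.classify import classify_dataset, misexpression_proportion, write_summary
from asediverge.testing import ContrastResult, ContrastSet

from common import RESULTS, TESTING, outdir


def load_contrasts(path) -> ContrastSet:
    results = {}
    for key in ("P", "H", "T", "FR", "FS"):
        table = aio.read_table(path / f"contrast_{key}.tsv")
        table["informative"] = table["informative"].astype(bool)
        results[key] = ContrastResult(key, table)
    return ContrastSet(**results)


def main() -> None:
    out = outdir("classification")
    contrasts = load_contrasts(RESULTS / "contrasts")
    classifications = classify_dataset(contrasts, TESTING)
    aio.write_table(classifications, out / "classification.tsv")
    write_summary(classifications, out / "category_proportions.json")
    mis = misexpression_proportion(classifications)
    (out / "misexpression.json").write_text(json.dumps(mis, indent=2) + "\n")

    truth = aio.read_truth(RESULTS / "benchmark" / "truth.tsv")
    print("regulatory-pattern proportions:")
    print(classifications.regulation.value_counts(normalize=True).round(4).to_string())
    print("inheritance-mode proportions:")
    print(classifications.inheritance.value_counts(normalize=True).round(4).to_string())
    print(f"misexpression proportion (over+under / informative): {mis['proportion']:.4f}")

    crosstab = pd.crosstab(truth.true_regulatory_category, classifications.regulation)
    crosstab.to_csv(out / "recovery_crosstab.tsv", sep="\t")
    noncons = truth.true_regulatory_category != "conserved"
    recovery = (classifications.regulation[noncons] == truth.true_regulatory_category[noncons]).mean()
    print(f"non-conserved true-category recovery: {recovery:.4f}")
    print(f"wrote classification artifacts to {out}")


if __name__ == "__main__":
    main()
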