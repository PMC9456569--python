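"""Decision tables for inheritance modes and cis/trans regulatory patterns.

Regulatory pattern, from three tests — parental divergence (P), hybrid
allelic imbalance (H), and their difference (T, the trans component):

=========  =========  =========  ==================================
sig P      sig H      sig T      pattern
=========  =========  =========  ==================================
no         no         no         conserved
yes        yes        no         all cis
yes        no         yes        all trans
yes        yes        yes        cis + trans (ratio signs agree)
                                 cis x trans (ratio signs oppose)
no         yes        yes        compensatory
any other combination            ambiguous
=========  =========  =========  ==================================

Inheritance mode, from parental divergence (P) and the hybrid-total
versus each parent (FR: F1 over parent R, FS: F1 over parent S):
conserved when nothing is significant; over/underdominant when the
hybrid differs from both parents in the same direction (misexpression —
no parental divergence required); additive when the hybrid sits between
two diverged parents, differing from both; dominant when the hybrid
tracks one parent and differs only from the other; otherwise ambiguous.
A gene uninformative in any required contrast is uninformative.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TestConfig
from .testing import ContrastResult, ContrastSet

REGULATION_LABELS = (
    "conserved",
    "all_cis",
    "all_trans",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
    "ambiguous",
    "uninformative",
)

INHERITANCE_LABELS = (
    "conserved",
    "additive",
    "RR_dominant",
    "SS_dominant",
    "overdominant",
    "underdominant",
    "ambiguous",
    "uninformative",
)


def _significant(result: ContrastResult, config: TestConfig) -> pd.Series:
    col = "padj" if config.use_adjusted else "p"
    return (result.table[col] < config.alpha).fillna(False) & result.table["informative"]


def classify_regulation(
    result_p: ContrastResult,
    result_h: ContrastResult,
    result_t: ContrastResult,
    config: TestConfig | None = None,
) -> pd.Series:
    """Apply the regulatory-pattern decision table gene-wise (vectorized)."""
    config = config or TestConfig()
    tp, th, tt = result_p.table, result_h.table, result_t.table
    if not (tp.index.equals(th.index) and tp.index.equals(tt.index)):
        raise ValueError("contrast inputs cover different gene sets")

    sig_p = _significant(result_p, config).to_numpy()
    sig_h = _significant(result_h, config).to_numpy()
    sig_t = _significant(result_t, config).to_numpy()
    informative = (
        tp["informative"] & th["informative"] & tt["informative"]
    ).to_numpy()
    l_p = tp["L"].to_numpy()
    l_h = th["L"].to_numpy()
    l_t = tt["L"].to_numpy()

    if config.interaction_sign_rule == "parental_vs_allelic":
        signs_agree = np.sign(l_p) == np.sign(l_h)
        sign_defined = (l_p != 0) & (l_h != 0)
    else:  # allelic_vs_trans
        signs_agree = np.sign(l_h) == np.sign(l_t)
        sign_defined = (l_h != 0) & (l_t != 0)

    out = np.full(len(tp), "ambiguous", dtype=object)
    out[~sig_p & ~sig_h & ~sig_t] = "conserved"
    out[sig_p & sig_h & ~sig_t] = "all_cis"
    out[sig_p & ~sig_h & sig_t] = "all_trans"
    all_sig = sig_p & sig_h & sig_t
    out[all_sig & sign_defined & signs_agree] = "cis_plus_trans"
    out[all_sig & sign_defined & ~signs_agree] = "cis_times_trans"
    out[all_sig & ~sign_defined] = "ambiguous"  # exact-zero L with a significant flag
    out[~sig_p & sig_h & sig_t] = "compensatory"
    out[~informative] = "uninformative"
    return pd.Series(out, index=tp.index, name="regulation")


def classify_inheritance(
    result_p: ContrastResult,
    result_fr: ContrastResult,
    result_fs: ContrastResult,
    config: TestConfig | None = None,
) -> pd.Series:
    """Apply the inheritance-mode decision table gene-wise (vectorized)."""
    config = config or TestConfig()
    tp, tfr, tfs = result_p.table, result_fr.table, result_fs.table
    if not (tp.index.equals(tfr.index) and tp.index.equals(tfs.index)):
        raise ValueError("contrast inputs cover different gene sets")

    sig_p = _significant(result_p, config).to_numpy()
    sig_fr = _significant(result_fr, config).to_numpy()
    sig_fs = _significant(result_fs, config).to_numpy()
    informative = (
        tp["informative"] & tfr["informative"] & tfs["informative"]
    ).to_numpy()
    l_fr = tfr["L"].to_numpy()
    l_fs = tfs["L"].to_numpy()

    out = np.full(len(tp), "ambiguous", dtype=object)
    out[~sig_p & ~sig_fr & ~sig_fs] = "conserved"
    both = sig_fr & sig_fs
    out[both & (l_fr > 0) & (l_fs > 0)] = "overdominant"
    out[both & (l_fr < 0) & (l_fs < 0)] = "underdominant"
    opposite = both & (np.sign(l_fr) != np.sign(l_fs)) & (l_fr != 0) & (l_fs != 0)
    out[sig_p & opposite] = "additive"
    out[sig_p & ~sig_fr & sig_fs] = "RR_dominant"
    out[sig_p & sig_fr & ~sig_fs] = "SS_dominant"
    out[~informative] = "uninformative"
    return pd.Series(out, index=tp.index, name="inheritance")


def classify_dataset(contrasts: ContrastSet, config: TestConfig | None = None) -> pd.DataFrame:
    """Both classifications plus the underlying flags and log2 ratios.

    Returns a frame indexed by gene with columns L_P, L_H, L_T, L_FR,
    L_FS, sig_* booleans, ``inheritance`` and ``regulation``.
    """
    config = config or TestConfig()
    required = contrasts.as_dict()
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ValueError(f"missing contrast families: {missing}")
    out = pd.DataFrame(index=contrasts.P.table.index)
    for key, res in required.items():
        out[f"L_{key}"] = res.table["L"]
        out[f"sig_{key}"] = _significant(res, config)
    out["regulation"] = classify_regulation(contrasts.P, contrasts.H, contrasts.T, config)
    out["inheritance"] = classify_inheritance(contrasts.P, contrasts.FR, contrasts.FS, config)
    return out


def category_proportions(classifications: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Proportions of each label over all genes (uninformative included)."""
    n = len(classifications)
    summary: dict[str, dict[str, float]] = {}
    for column, labels in (("regulation", REGULATION_LABELS), ("inheritance", INHERITANCE_LABELS)):
        counts = classifications[column].value_counts()
        summary[column] = {label: float(counts.get(label, 0)) / n if n else 0.0 for label in labels}
    return summary


def write_summary(classifications: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(category_proportions(classifications), indent=2) + "\n")


def misexpression_proportion(classifications: pd.DataFrame) -> dict[str, float]:
    """Fraction of informative genes called over- or underdominant.

    Misexpression means hybrid expression outside the parental range.
    Returns the total plus the per-direction breakdown; all values are
    NaN when no gene is informative.
    """
    informative = classifications["inheritance"] != "uninformative"
    n = int(informative.sum())
    if n == 0:
        return {"proportion": float("nan"), "over": float("nan"), "under": float("nan"), "n_informative": 0}
    modes = classifications.loc[informative, "inheritance"]
    over = float((modes == "overdominant").sum()) / n
    under = float((modes == "underdominant").sum()) / n
    return {"proportion": over + under, "over": over, "under": under, "n_informative": n}
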