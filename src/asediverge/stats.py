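"""Divergence magnitude by regulatory category, diagnostics, correlation.

The magnitude of expression divergence for a gene is the absolute
parental log2 fold change |log2(RR/SS)|; grouping it by inferred
regulatory pattern shows which kinds of regulatory change move
expression furthest (same-direction cis + trans changes add up, while
compensatory changes cancel).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .testing import ContrastResult, adjust_pvalues


def divergence_magnitude(result_p: ContrastResult, classifications: pd.DataFrame) -> pd.DataFrame:
    """|L_P| per informative gene joined with its regulatory category."""
    table = result_p.table
    joined = pd.DataFrame(
        {"magnitude": table["L"].abs(), "regulation": classifications["regulation"]},
        index=table.index,
    )
    keep = table["informative"] & (joined["regulation"] != "uninformative")
    dropped = int((~keep).sum())
    if dropped:
        joined = joined.loc[keep]
    return joined


def rank_compare(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of two magnitude samples."""
    stat, p = stats.ranksums(np.asarray(x, float), np.asarray(y, float))
    return float(stat), float(p)


def compare_categories(divergence: pd.DataFrame, min_genes: int = 3) -> pd.DataFrame:
    """Pairwise rank-sum tests of divergence magnitude between categories.

    Shapiro–Wilk normality p-values are recorded per category (they frame
    how the comparison should be reported; magnitudes of count ratios are
    rarely normal) and the Wilcoxon rank-sum test is run for every pair of
    categories with at least ``min_genes`` genes, BH-adjusted across
    pairs. Categories below the threshold are skipped with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    shapiro_p: dict[str, float] = {}
    for category, sub in divergence.groupby("regulation"):
        values = sub["magnitude"].to_numpy()
        if len(values) < min_genes:
            warnings.warn(
                f"category {category!r} has {len(values)} genes (< {min_genes}); skipped",
                RuntimeWarning,
            )
            continue
        groups[str(category)] = values
        shapiro_p[str(category)] = float(stats.shapiro(values).pvalue) if len(values) >= 3 else float("nan")
    if len(groups) < 2:
        raise ValueError("need at least two categories with enough genes to compare")

    rows = []
    for cat_a, cat_b in itertools.combinations(sorted(groups), 2):
        stat, p = rank_compare(groups[cat_a], groups[cat_b])
        rows.append(
            {
                "category_a": cat_a,
                "category_b": cat_b,
                "n_a": len(groups[cat_a]),
                "n_b": len(groups[cat_b]),
                "median_a": float(np.median(groups[cat_a])),
                "median_b": float(np.median(groups[cat_b])),
                "median_diff": float(np.median(groups[cat_a]) - np.median(groups[cat_b])),
                "shapiro_p_a": shapiro_p[cat_a],
                "shapiro_p_b": shapiro_p[cat_b],
                "stat": stat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = adjust_pvalues(out["p"].to_numpy())
    return out


def vst_transform(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Shifted-log variance-stabilizing transform: log2(count/sf + 1)."""
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    return pd.DataFrame(np.log2(values / sf + 1.0), index=counts.index, columns=counts.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray


def run_pca(matrix: pd.DataFrame, n_components: int | None = None, n_top_genes: int = 500) -> PCAResult:
    """PCA of samples from a genes-x-samples expression matrix.

    Genes are centered, the ``n_top_genes`` most variable genes are kept,
    and the sample scores come from the SVD of the centered matrix.
    Variance explained is relative to the total variance of the selected
    centered matrix, so it is non-increasing and sums to <= 1 (to 1 when
    all components are retained). Requesting more components than samples
    reduces the count with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    variances = matrix.var(axis=1)
    if n_top_genes and n_top_genes < len(matrix):
        keep = variances.sort_values(ascending=False).index[:n_top_genes]
        sub = matrix.loc[keep]
    else:
        sub = matrix
    centered = sub.sub(sub.mean(axis=1), axis=0)
    x = centered.to_numpy(dtype=float).T  # samples x genes

    max_k = min(x.shape)
    k = n_components if n_components is not None else max_k
    if k > max_k:
        warnings.warn(f"reducing n_components from {k} to {max_k}", RuntimeWarning)
        k = max_k
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(len(s)):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    total_ss = float((x**2).sum())
    var_explained = (s[:k] ** 2) / total_ss if total_ss > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(vt[:k].T, index=sub.index, columns=comp_names),
        variance_explained=var_explained,
    )


def correlate_expression_phenotype(
    expression: pd.DataFrame,
    phenotype: pd.Series,
    n_permutation_max: int = 9,
) -> pd.DataFrame:
    """Spearman correlation of each gene's per-group expression with a phenotype.

    With fewer than 10 paired groups the p-value is the exact permutation
    null (all orderings of the phenotype enumerated); otherwise the
    asymptotic p from the rank correlation is used. Genes or phenotypes
    with zero rank variance get NaN rho ("undefined") rather than a value.
    """
    groups = [g for g in expression.columns if g in phenotype.index]
    if len(groups) < 3:
        raise ValueError("need at least three paired groups")
    pheno = phenotype.loc[groups].to_numpy(dtype=float)
    pheno_ranks = stats.rankdata(pheno)
    exact = len(groups) <= n_permutation_max

    perm_ranks = None
    if exact:
        perms = np.array(list(itertools.permutations(pheno_ranks)))
        perm_ranks = perms - perms.mean(axis=1, keepdims=True)
        perm_norm = np.linalg.norm(perm_ranks, axis=1)

    rows = []
    for gene, values in expression[groups].iterrows():
        v = values.to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(pheno) == 0:
            rows.append((gene, np.nan, np.nan))
            continue
        if exact:
            r = stats.rankdata(v)
            rc = r - r.mean()
            rho_all = perm_ranks @ rc / (perm_norm * np.linalg.norm(rc))
            rho = float(stats.spearmanr(v, pheno).statistic)
            p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        else:
            res = stats.spearmanr(v, pheno)
            rho, p = float(res.statistic), float(res.pvalue)
        rows.append((gene, rho, p))
    return pd.DataFrame(rows, columns=["gene", "rho", "p"]).set_index("gene")
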