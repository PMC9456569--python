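"""Normalization and per-gene negative-binomial contrast tests.

The test is a transparent NB Wald test on the log2 ratio of group means:
counts are normalized by median-of-ratios size factors, dispersion is a
method-of-moments estimate shrunk toward the across-gene trend, and the
standard error of each group's mean comes from the NB variance function
var = mu + alpha * mu**2 propagated to the log2 scale. This mirrors the
model used by the standard count-based DE frameworks while keeping every
number reproducible from first principles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import TestConfig
from .matrix import CountMatrix

LN2 = np.log(2.0)


class NormalizationError(ValueError):
    pass


def estimate_size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j the factor is the median over genes of
    counts[g, j] / geometric-mean_g, taken over genes with strictly
    positive counts in every sample.
    """
    frame = counts.data if isinstance(counts, CountMatrix) else counts
    values = frame.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios normalization is undefined (check library quality "
            "or supply size factors directly)"
        )
    logs = np.log(values[positive])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=frame.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame | CountMatrix,
    size_factors: pd.Series,
    groups: pd.Series | None = None,
    floor: float = 1e-4,
    shrink: float = 1.0,
) -> pd.Series:
    """Per-gene NB dispersion by pooled method-of-moments.

    Within each group with >= 2 replicates, alpha is (s^2 - m) / m^2 on
    normalized counts; estimates are pooled across groups weighted by
    degrees of freedom, floored, then shrunk toward the across-gene mean
    on the log scale with weight ``shrink`` (1 pools fully — appropriate
    when genes share a dispersion, as replicate-level moment estimates are
    extremely noisy; 0 keeps the raw per-gene values).
    """
    frame = counts.data if isinstance(counts, CountMatrix) else counts
    if isinstance(counts, CountMatrix) and groups is None:
        groups = counts.samples["group"]
    if groups is None:
        groups = pd.Series("all", index=frame.columns)
    norm = frame.to_numpy(dtype=float) / size_factors.loc[frame.columns].to_numpy()

    num = np.zeros(frame.shape[0])
    den = 0.0
    trend_num = trend_den = 0.0
    for group in groups.unique():
        cols = np.flatnonzero((groups == group).to_numpy())
        n = len(cols)
        if n < 2:
            continue
        raw_g, tn, td = _moment_dispersion(norm[:, cols])
        num += (n - 1) * raw_g
        den += n - 1
        trend_num += tn
        trend_den += td
    if den == 0.0:
        warnings.warn(
            "no group has >= 2 replicates; falling back to a global prior dispersion",
            RuntimeWarning,
        )
        return pd.Series(0.05, index=frame.index, name="dispersion")
    raw = num / den
    trend = trend_num / trend_den if trend_den > 0 else floor
    return pd.Series(_shrink_dispersion(raw, trend, floor, shrink), index=frame.index, name="dispersion")


def _moment_dispersion(sub: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-gene MoM dispersions plus the shared-trend moment sums.

    Returns the raw (unfloored) per-gene estimates (s^2 - m) / m^2 and the
    numerator/denominator of the across-gene ratio-of-sums estimator
    sum(s^2 - m) / sum(m^2 - s^2/n). The latter is the trend target: it
    avoids the per-gene division, whose correlated numerator and
    denominator bias a mean (or median) of per-gene ratios at
    replicate-level degrees of freedom, and its denominator correction
    -s^2/n makes m^2 unbiased for the squared true mean.
    """
    n = sub.shape[1]
    m = sub.mean(axis=1)
    v = sub.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (v - m) / m**2
    a = np.where(np.isfinite(a), a, 0.0)
    trend_num = float(np.sum(v - m))
    trend_den = float(np.sum(np.maximum(m**2 - v / n, 0.0)))
    return a, trend_num, trend_den


def _shrink_dispersion(raw: np.ndarray, trend: float, floor: float, shrink: float) -> np.ndarray:
    alpha = np.maximum(raw, floor)
    if shrink > 0:
        trend = max(trend, floor)
        alpha = np.exp((1.0 - shrink) * np.log(alpha) + shrink * np.log(trend))
    return np.maximum(alpha, floor)


def estimate_dispersion_by_group(
    counts: CountMatrix,
    size_factors: pd.Series,
    floor: float = 1e-4,
    shrink: float = 1.0,
) -> dict[str, pd.Series]:
    """Per-gene dispersion estimated separately within each sample group.

    Groups differ systematically in overdispersion here — e.g. allele-level
    columns carry assignment variability on top of library noise, while a
    hybrid total that is the sum of separately-fluctuating read classes is
    tighter than a single library draw — so each contrast should use the
    dispersions of the groups it actually compares.
    """
    frame = counts.data
    groups = counts.samples["group"]
    norm = frame.to_numpy(dtype=float) / size_factors.loc[frame.columns].to_numpy()
    out: dict[str, pd.Series] = {}
    for group in groups.unique():
        cols = np.flatnonzero((groups == group).to_numpy())
        if len(cols) < 2:
            warnings.warn(
                f"group {group!r} has a single replicate; using a global prior dispersion",
                RuntimeWarning,
            )
            out[group] = pd.Series(0.05, index=frame.index, name="dispersion")
            continue
        raw, trend_num, trend_den = _moment_dispersion(norm[:, cols])
        trend = trend_num / trend_den if trend_den > 0 else floor
        out[group] = pd.Series(
            _shrink_dispersion(raw, trend, floor, shrink), index=frame.index, name="dispersion"
        )
    return out


@dataclass
class ContrastResult:
    """Per-gene results of one named contrast (frame indexed by gene)."""

    name: str
    table: pd.DataFrame  # columns: L, se, stat, p, padj, informative

    def __post_init__(self) -> None:
        missing = {"L", "se", "stat", "p", "padj", "informative"} - set(self.table.columns)
        if missing:
            raise ValueError(f"contrast table lacks columns {sorted(missing)}")


def _model_variance(m: np.ndarray, cols: np.ndarray, sf: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Model-based variance of a group's mean normalized count.

    K_s ~ NB(sf_s * m, alpha)  =>  Var(mean_s K_s / sf_s)
    = (1/n^2) * sum_s (m / sf_s + alpha * m^2).
    """
    n = len(cols)
    inv_sf_sum = float(np.sum(1.0 / sf[cols]))
    return (m * inv_sf_sum + alpha * m**2 * n) / n**2


def test_contrast(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series | tuple[pd.Series, pd.Series],
    group_a: str | list[str],
    group_b: str | list[str],
    config: TestConfig | None = None,
    name: str | None = None,
) -> ContrastResult:
    """NB Wald test of group A over group B, one row per gene.

    L is the log2 ratio of mean normalized counts (pseudocount applied to
    both means only when one is zero); se propagates the NB variance of
    each group mean to the log2 scale; p is two-sided normal on L/se.
    Genes whose mean normalized count falls below ``min_mean_count`` in
    either group are flagged uninformative and excluded from BH.
    ``dispersion`` is one per-gene series shared by both groups, or a
    ``(disp_a, disp_b)`` pair when the groups have their own dispersions.
    """
    config = config or TestConfig()
    if isinstance(counts, CountMatrix):
        frame = counts.data
        cols_a = counts.columns_for(group_a) if isinstance(group_a, str) else list(group_a)
        cols_b = counts.columns_for(group_b) if isinstance(group_b, str) else list(group_b)
    else:
        frame = counts
        if isinstance(group_a, str) or isinstance(group_b, str):
            raise ValueError("with a bare frame, groups must be explicit column lists")
        cols_a, cols_b = list(group_a), list(group_b)
    if not cols_a or not cols_b:
        raise ValueError("both groups must contain at least one sample")

    sf = size_factors.loc[frame.columns].to_numpy()
    if isinstance(dispersion, tuple):
        disp_a, disp_b = dispersion
    else:
        disp_a = disp_b = dispersion
    alpha_a = disp_a.loc[frame.index].to_numpy()
    alpha_b = disp_b.loc[frame.index].to_numpy()
    norm = frame.to_numpy(dtype=float) / sf
    idx_a = np.array([frame.columns.get_loc(c) for c in cols_a])
    idx_b = np.array([frame.columns.get_loc(c) for c in cols_b])

    m_a = norm[:, idx_a].mean(axis=1)
    m_b = norm[:, idx_b].mean(axis=1)

    # pseudocount applied to both means only when either is zero, keeping
    # the A/B swap symmetry exact; variances use the adjusted means
    zero = (m_a == 0) | (m_b == 0)
    m_a_adj = np.where(zero, m_a + config.pseudocount, m_a)
    m_b_adj = np.where(zero, m_b + config.pseudocount, m_b)
    var_a = _model_variance(m_a_adj, idx_a, sf, alpha_a)
    var_b = _model_variance(m_b_adj, idx_b, sf, alpha_b)

    L = np.log2(m_a_adj / m_b_adj)
    se = np.sqrt(var_a / m_a_adj**2 + var_b / m_b_adj**2) / LN2
    se = np.maximum(se, 1e-12)
    stat = L / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    informative = (m_a >= config.min_mean_count) & (m_b >= config.min_mean_count)

    p_for_adjust = np.where(informative, p, np.nan)
    padj = adjust_pvalues(p_for_adjust)
    table = pd.DataFrame(
        {
            "L": L,
            "se": se,
            "stat": stat,
            "p": p,
            "padj": padj,
            "informative": informative,
        },
        index=frame.index,
    )
    return ContrastResult(name or "contrast", table)


def test_ratio_difference(result_p: ContrastResult, result_h: ContrastResult, name: str = "T") -> ContrastResult:
    """Trans test: difference of the parental and allelic log2 ratios.

    L_T = L_P - L_H with se_T = sqrt(se_P^2 + se_H^2); a significant L_T
    indicates parental divergence not explained by allelic imbalance.
    """
    tp, th = result_p.table, result_h.table
    if not tp.index.equals(th.index):
        raise ValueError("contrast inputs cover different gene sets")
    L = tp["L"] - th["L"]
    se = np.sqrt(tp["se"] ** 2 + th["se"] ** 2)
    stat = L / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    informative = tp["informative"] & th["informative"]
    padj = adjust_pvalues(np.where(informative, p, np.nan))
    table = pd.DataFrame(
        {"L": L, "se": se, "stat": stat, "p": p, "padj": padj, "informative": informative},
        index=tp.index,
    )
    return ContrastResult(name, table)


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini–Hochberg step-up; NaNs pass through untouched."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if ((arr[mask] < 0) | (arr[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


@dataclass
class ContrastSet:
    """The five standard contrasts of the hybrid design."""

    P: ContrastResult  # parent_R vs parent_S (log2 ratio = c + t)
    H: ContrastResult  # hybrid_allele_R vs hybrid_allele_S (log2 ratio = c)
    T: ContrastResult  # L_P - L_H (trans component)
    FR: ContrastResult  # hybrid_total vs parent_R
    FS: ContrastResult  # hybrid_total vs parent_S
    size_factors: pd.Series = field(default=None, repr=False)
    dispersion: pd.Series = field(default=None, repr=False)

    def as_dict(self) -> dict[str, ContrastResult]:
        return {"P": self.P, "H": self.H, "T": self.T, "FR": self.FR, "FS": self.FS}


def run_standard_contrasts(counts: CountMatrix, config: TestConfig | None = None) -> ContrastSet:
    """Normalize, estimate dispersion, and run all five contrasts.

    Hybrid allele columns are normalized as separate samples — their size
    factors absorb both sequencing depth and the unassigned-read fraction.
    With ``dispersion_mode='per_group'`` (the default) each contrast uses
    the dispersions estimated within the two groups it compares; with
    ``'pooled'`` a single per-gene dispersion pooled across all groups.
    """
    config = config or TestConfig()
    sf = estimate_size_factors(counts)
    if config.dispersion_mode == "per_group":
        by_group = estimate_dispersion_by_group(
            counts, sf, floor=config.dispersion_floor, shrink=config.dispersion_shrink
        )
        disp = pd.DataFrame(by_group)

        def pair(a: str, b: str) -> tuple[pd.Series, pd.Series]:
            return by_group[a], by_group[b]

    else:
        pooled = estimate_dispersion(
            counts, sf, floor=config.dispersion_floor, shrink=config.dispersion_shrink
        )
        disp = pooled

        def pair(a: str, b: str) -> tuple[pd.Series, pd.Series]:
            return pooled, pooled

    p = test_contrast(counts, sf, pair("parent_R", "parent_S"), "parent_R", "parent_S", config, name="P")
    h = test_contrast(
        counts, sf, pair("hybrid_allele_R", "hybrid_allele_S"),
        "hybrid_allele_R", "hybrid_allele_S", config, name="H",
    )
    t = test_ratio_difference(p, h, name="T")
    fr = test_contrast(counts, sf, pair("hybrid_total", "parent_R"), "hybrid_total", "parent_R", config, name="FR")
    fs = test_contrast(counts, sf, pair("hybrid_total", "parent_S"), "hybrid_total", "parent_S", config, name="FS")
    return ContrastSet(P=p, H=h, T=t, FR=fr, FS=fs, size_factors=sf, dispersion=disp)
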