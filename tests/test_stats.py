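import itertools
import math

import numpy as np
import pandas as pd
import pytest

from asediverge.stats import (
    compare_categories,
    correlate_expression_phenotype,
    divergence_magnitude,
    rank_compare,
    run_pca,
    vst_transform,
)
from asediverge.testing import ContrastResult


def _parental(L, informative=True):
    L = np.asarray(L, dtype=float)
    informative = np.broadcast_to(np.asarray(informative, dtype=bool), L.shape)
    table = pd.DataFrame(
        {
            "L": L,
            "se": 0.1,
            "stat": L / 0.1,
            "p": 0.5,
            "padj": 0.5,
            "informative": informative,
        },
        index=[f"g{i}" for i in range(len(L))],
    )
    return ContrastResult("P", table)


def _classes(categories):
    return pd.DataFrame(
        {"regulation": categories, "inheritance": ["conserved"] * len(categories)},
        index=[f"g{i}" for i in range(len(categories))],
    )


class TestDivergenceMagnitude:
    def test_equal_parents_give_zero(self):
        out = divergence_magnitude(_parental([0.0]), _classes(["conserved"]))
        assert out.magnitude.iloc[0] == 0.0

    def test_fourfold_ratio_gives_two(self):
        out = divergence_magnitude(_parental([2.0, -2.0]), _classes(["all_cis", "all_cis"]))
        assert (out.magnitude == 2.0).all()

    def test_uninformative_genes_dropped(self):
        out = divergence_magnitude(
            _parental([1.0, 1.0], [True, False]), _classes(["all_cis", "all_cis"])
        )
        assert len(out) == 1

    def test_category_means_track_expected_magnitude(self, effect_dataset):
        from asediverge.classify import classify_dataset
        from asediverge.testing import run_standard_contrasts

        contrasts = run_standard_contrasts(effect_dataset.counts)
        truth = effect_dataset.truth_frame()
        div = divergence_magnitude(contrasts.P, classify_dataset(contrasts))
        joined = div.join(truth)
        for category, expected in [("cis_plus_trans", 4.0), ("all_cis", 2.0), ("compensatory", 0.0)]:
            sub = joined[joined.true_regulatory_category == category]
            assert sub.magnitude.mean() == pytest.approx(expected, abs=0.3)


class TestCompareCategories:
    def test_same_distribution_rarely_significant(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            div = pd.DataFrame(
                {
                    "magnitude": np.abs(rng.normal(1, 0.5, 200)),
                    "regulation": ["all_cis"] * 100 + ["all_trans"] * 100,
                }
            )
            out = compare_categories(div)
            hits += int((out.padj < 0.05).any())
        assert hits <= 3  # ~5% nominal; 3sigma-ish slack on 20 runs

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(1)
        div = pd.DataFrame(
            {
                "magnitude": np.concatenate(
                    [np.abs(rng.normal(0.5, 0.3, 200)), np.abs(rng.normal(1.5, 0.3, 200))]
                ),
                "regulation": ["compensatory"] * 200 + ["cis_plus_trans"] * 200,
            }
        )
        out = compare_categories(div)
        assert (out.padj < 0.05).all()
        assert out.median_diff.iloc[0] != 0

    def test_self_comparison_is_exactly_null(self):
        x = np.array([0.3, 0.7, 1.1, 1.9, 2.5])
        stat, p = rank_compare(x, x)
        assert stat == 0.0 and p == 1.0

    def test_small_category_skipped_with_warning(self):
        div = pd.DataFrame(
            {
                "magnitude": [1.0, 2.0, 0.5, 0.6, 0.7, 0.8],
                "regulation": ["all_cis", "all_cis", "all_trans", "all_trans", "all_trans", "all_trans"],
            }
        )
        with pytest.warns(RuntimeWarning, match="skipped"):
            with pytest.raises(ValueError):
                compare_categories(div)

    def test_invariant_under_gene_relabeling(self):
        rng = np.random.default_rng(2)
        div = pd.DataFrame(
            {
                "magnitude": rng.random(60),
                "regulation": ["a"] * 30 + ["b"] * 30,
            },
            index=[f"g{i}" for i in range(60)],
        )
        shuffled = div.sample(frac=1.0, random_state=3)
        pd.testing.assert_frame_equal(
            compare_categories(div), compare_categories(shuffled)
        )


class TestVst:
    def test_zero_count_maps_to_zero(self):
        frame = pd.DataFrame({"s": [0]})
        out = vst_transform(frame, pd.Series([1.0], index=["s"]))
        assert out.iloc[0, 0] == 0.0

    def test_count_three_unit_factor_gives_two(self):
        frame = pd.DataFrame({"s": [3]})
        out = vst_transform(frame, pd.Series([1.0], index=["s"]))
        assert out.iloc[0, 0] == pytest.approx(2.0)

    def test_negative_counts_rejected(self):
        frame = pd.DataFrame({"s": [-1]})
        with pytest.raises(ValueError):
            vst_transform(frame, pd.Series([1.0], index=["s"]))

    def test_variance_flattened_relative_to_raw_counts(self, null_dataset):
        from asediverge.testing import estimate_size_factors

        counts = null_dataset.counts.data
        sf = estimate_size_factors(counts)
        vst = vst_transform(counts, sf)
        raw_mean, raw_var = counts.mean(axis=1), counts.var(axis=1)
        vst_mean, vst_var = vst.mean(axis=1), vst.var(axis=1)
        slope_raw = np.polyfit(raw_mean, raw_var, 1)[0]
        slope_vst = np.polyfit(vst_mean, vst_var, 1)[0]
        assert abs(slope_vst) < abs(slope_raw)


class TestPca:
    @staticmethod
    def _matrix(seed=0, n_genes=300, n_samples=6, shift=0.0):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 1, (n_genes, n_samples))
        if shift:
            base[: n_genes // 5, n_samples // 2 :] += shift
        return pd.DataFrame(
            base, index=[f"g{i}" for i in range(n_genes)], columns=[f"s{i}" for i in range(n_samples)]
        )

    def test_duplicated_samples_get_identical_scores(self):
        m = self._matrix()
        m["dup"] = m["s0"]
        pca = run_pca(m, n_top_genes=0)
        np.testing.assert_allclose(pca.scores.loc["s0"], pca.scores.loc["dup"], atol=1e-8)

    def test_group_shift_separates_on_pc1(self):
        m = self._matrix(shift=2.0)
        pca = run_pca(m)
        pc1 = pca.scores["PC1"]
        a, b = pc1[:3], pc1[3:]
        assert a.max() < b.min() or b.max() < a.min()

    def test_variance_explained_sorted_and_bounded(self):
        pca = run_pca(self._matrix(seed=1))
        ve = pca.variance_explained
        assert (np.diff(ve) <= 1e-12).all()
        assert ve.sum() <= 1.0 + 1e-9

    def test_full_rank_reconstruction(self):
        m = self._matrix(seed=2, n_genes=50)
        pca = run_pca(m, n_top_genes=0)
        centered = m.sub(m.mean(axis=1), axis=0).to_numpy().T
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_too_many_components_reduced_with_warning(self):
        with pytest.warns(RuntimeWarning, match="reducing"):
            pca = run_pca(self._matrix(), n_components=50)
        assert pca.scores.shape[1] <= 6


class TestSpearman:
    @staticmethod
    def _expr(rows, groups):
        return pd.DataFrame(rows, columns=groups, index=[f"g{i}" for i in range(len(rows))])

    def test_monotone_increasing_is_one(self):
        groups = list("abcde")
        expr = self._expr([[1, 2, 3, 4, 5]], groups)
        pheno = pd.Series([10, 20, 30, 40, 50], index=groups)
        out = correlate_expression_phenotype(expr, pheno)
        assert out.rho.iloc[0] == pytest.approx(1.0)
        assert out.p.iloc[0] == pytest.approx(2 / 120)  # two of 5! orderings at |rho|=1

    def test_monotone_decreasing_is_minus_one(self):
        groups = list("abcde")
        expr = self._expr([[5, 4, 3, 2, 1]], groups)
        pheno = pd.Series([1, 2, 3, 4, 5], index=groups)
        out = correlate_expression_phenotype(expr, pheno)
        assert out.rho.iloc[0] == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force_ranks(self):
        groups = list("abcde")
        values = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        pheno_values = np.array([2.0, 2.0, 1.0, 4.0, 3.0])
        expr = self._expr([values], groups)
        pheno = pd.Series(pheno_values, index=groups)
        out = correlate_expression_phenotype(expr, pheno)

        def average_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = average_ranks(values), average_ranks(pheno_values)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.rho.iloc[0] == pytest.approx(expected)

    def test_constant_vector_reported_missing(self):
        groups = list("abcd")
        expr = self._expr([[3, 3, 3, 3]], groups)
        pheno = pd.Series([1, 2, 3, 4], index=groups)
        out = correlate_expression_phenotype(expr, pheno)
        assert np.isnan(out.rho.iloc[0])

    def test_fewer_than_three_groups_rejected(self):
        expr = self._expr([[1, 2]], ["a", "b"])
        pheno = pd.Series([1, 2], index=["a", "b"])
        with pytest.raises(ValueError):
            correlate_expression_phenotype(expr, pheno)
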