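import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asediverge import io as aio
from asediverge.assign import (
    assign_read,
    assign_sam,
    assignment_summary,
    count_alleles,
    find_diagnostic_sites,
)


def _variants(rows):
    return pd.DataFrame(rows, columns=["gene", "pos", "alleles"])


SITES = pd.DataFrame(
    {"gene": ["g1", "g1"], "pos": [10, 20], "allele_R": ["A", "A"], "allele_S": ["G", "G"]}
)


class TestFindDiagnosticSites:
    def test_fixed_different_alleles_are_diagnostic(self):
        out = find_diagnostic_sites(
            _variants([("g", 100, "A")]), _variants([("g", 100, "G")])
        )
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.gene, row.pos, row.allele_R, row.allele_S) == ("g", 100, "A", "G")

    def test_identical_fixed_alleles_excluded(self):
        out = find_diagnostic_sites(
            _variants([("g", 100, "A")]), _variants([("g", 100, "A")])
        )
        assert out.empty

    def test_heterozygous_site_excluded_regardless_of_other_species(self):
        out = find_diagnostic_sites(
            _variants([("g", 100, "A/G")]), _variants([("g", 100, "C")])
        )
        assert out.empty

    def test_site_missing_from_one_species_excluded(self):
        out = find_diagnostic_sites(
            _variants([("g", 100, "A"), ("g", 200, "C")]), _variants([("g", 100, "G")])
        )
        assert list(out.pos) == [100]

    def test_output_sorted_by_gene_then_position(self):
        r = _variants([("b", 5, "A"), ("a", 9, "C"), ("a", 2, "T")])
        s = _variants([("b", 5, "G"), ("a", 9, "G"), ("a", 2, "G")])
        out = find_diagnostic_sites(r, s)
        assert list(zip(out.gene, out.pos)) == [("a", 2), ("a", 9), ("b", 5)]


class TestAssignRead:
    @pytest.mark.parametrize(
        "observed,expected",
        [
            ({10: "A", 20: "A"}, "parent_R"),  # unanimous R
            ({10: "G", 20: "G"}, "parent_S"),  # unanimous S
            ({10: "A", 20: "G"}, "conflict"),  # one match to each parent
            ({}, "uninformative"),  # zero covered sites
            ({10: "C", 20: "T"}, "uninformative"),  # all bases match neither
            ({10: "A", 20: "C"}, "parent_R"),  # error base ignored
        ],
    )
    def test_assignment_categories(self, observed, expected):
        result = assign_read("r1", "g1", observed, SITES)
        assert result.category == expected
        assert (
            result.n_match_R + result.n_match_S + result.n_match_neither
            == result.n_sites_covered
        )

    @given(
        bases=st.lists(st.sampled_from("ACGT"), min_size=0, max_size=2),
    )
    @settings(max_examples=100, deadline=None)
    def test_categories_are_exhaustive_and_exclusive(self, bases):
        observed = {pos: base for pos, base in zip((10, 20), bases)}
        result = assign_read("r", "g1", observed, SITES)
        assert result.category in ("parent_R", "parent_S", "conflict", "uninformative")
        if result.n_sites_covered == 0 or (result.n_match_R == 0 and result.n_match_S == 0):
            assert result.category == "uninformative"
        elif result.n_match_R > 0 and result.n_match_S > 0:
            assert result.category == "conflict"


class TestCountAlleles:
    def test_simple_tally(self):
        assignments = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(4)],
                "sample": ["s1"] * 4,
                "gene": ["g"] * 4,
                "category": ["parent_R"] * 3 + ["parent_S"],
            }
        )
        out = count_alleles(assignments)
        row = out.loc[("g", "s1")]
        assert (row.count_R, row.count_S, row.count_total) == (3, 1, 4)

    def test_empty_input_gives_empty_matrix(self):
        out = count_alleles(pd.DataFrame(columns=["read_id", "sample", "gene", "category"]))
        assert out.empty

    def test_missing_gene_gets_zero_row(self):
        assignments = pd.DataFrame(
            {"read_id": ["r0"], "sample": ["s1"], "gene": ["g1"], "category": ["parent_R"]}
        )
        out = count_alleles(assignments, genes=["g1", "g2"])
        assert out.loc[("g2", "s1"), "count_total"] == 0

    def test_read_order_never_changes_counts(self):
        rng = np.random.default_rng(0)
        assignments = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(200)],
                "sample": rng.choice(["s1", "s2"], 200),
                "gene": rng.choice(["g1", "g2", "g3"], 200),
                "category": rng.choice(
                    ["parent_R", "parent_S", "conflict", "uninformative"], 200
                ),
            }
        )
        shuffled = assignments.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(count_alleles(assignments), count_alleles(shuffled))

    def test_partition_invariant(self):
        rng = np.random.default_rng(1)
        assignments = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(500)],
                "sample": rng.choice(["s1", "s2"], 500),
                "gene": rng.choice(["g1", "g2"], 500),
                "category": rng.choice(
                    ["parent_R", "parent_S", "conflict", "uninformative"], 500
                ),
            }
        )
        out = count_alleles(assignments)
        parts = out[["count_R", "count_S", "count_conflict", "count_uninformative"]].sum(axis=1)
        assert (parts == out["count_total"]).all()
        assert out["count_total"].sum() == 500


class TestAssignmentSummary:
    def _counts(self, rows):
        frame = pd.DataFrame(
            rows,
            columns=["gene", "sample", "count_R", "count_S", "count_conflict", "count_uninformative"],
        ).set_index(["gene", "sample"])
        frame["count_total"] = frame.sum(axis=1)
        return frame

    def test_equal_totals_give_half_bias(self):
        sample_table, gene_table = assignment_summary(
            self._counts([("g", "s1", 50, 50, 0, 0)])
        )
        assert sample_table.loc["s1", "bias"] == pytest.approx(0.5)

    def test_all_parent_r_degenerate(self):
        sample_table, _ = assignment_summary(self._counts([("g", "s1", 10, 0, 0, 0)]))
        assert sample_table.loc["s1", "bias"] == pytest.approx(1.0)
        assert sample_table.loc["s1", "fraction_assigned"] == pytest.approx(1.0)

    def test_zero_total_reported_missing_not_raised(self):
        sample_table, _ = assignment_summary(self._counts([("g", "s1", 0, 0, 0, 0)]))
        assert np.isnan(sample_table.loc["s1", "fraction_assigned"])
        assert np.isnan(sample_table.loc["s1", "bias"])

    def test_global_cis_shift_toward_s_detected(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(60):
            s = rng.binomial(300, 0.6)  # bias favoring species S
            rows.append((f"g{i}", "s1", 300 - s, s, 0, 20))
        _, gene_table = assignment_summary(self._counts(rows))
        assert gene_table["bias"].mean() < 0.5
        assert (gene_table["padj"] < 0.05).mean() > 0.5


class TestSamRoundAssignment:
    def test_error_free_assignment_recovers_truth_exactly(self, read_dataset, tmp_path):
        lengths = {g: len(s) for g, s in read_dataset.transcripts.items()}
        sam = tmp_path / "al.sam"
        aio.write_sam(read_dataset.reads, lengths, sam)
        aio.write_species_vcf(read_dataset.sites, tmp_path / "r.vcf", "R", contig_lengths=lengths)
        aio.write_species_vcf(read_dataset.sites, tmp_path / "s.vcf", "S", contig_lengths=lengths)
        sites = find_diagnostic_sites(
            aio.read_variant_table(tmp_path / "r.vcf"),
            aio.read_variant_table(tmp_path / "s.vcf"),
        )
        assignments = assign_sam(sam, sites)
        truth = pd.DataFrame(
            {
                "read_id": [r.read_id for r in read_dataset.reads],
                "origin": [r.true_origin for r in read_dataset.reads],
            }
        )
        merged = assignments.merge(truth, on="read_id")
        covered = merged[merged.n_sites_covered > 0]
        assert len(covered) > 0
        misassigned = (
            ((covered.category == "parent_R") & (covered.origin == "S"))
            | ((covered.category == "parent_S") & (covered.origin == "R"))
        )
        assert int(misassigned.sum()) == 0
        # error-free reads can never conflict
        assert (covered.category != "conflict").all()

    def test_counts_match_simulator_origin_tallies(self, read_dataset, tmp_path):
        lengths = {g: len(s) for g, s in read_dataset.transcripts.items()}
        sam = tmp_path / "al.sam"
        aio.write_sam(read_dataset.reads, lengths, sam)
        assignments = assign_sam(sam, read_dataset.sites)
        counted = count_alleles(assignments)
        truth_counts = (
            pd.DataFrame(
                {
                    "gene": [r.gene_id for r in read_dataset.reads],
                    "sample": [r.sample for r in read_dataset.reads],
                    "origin": [r.true_origin for r in read_dataset.reads],
                    "covered": [
                        any(
                            0 <= row.pos - 1 - r.start < len(r.sequence)
                            for row in read_dataset.sites[
                                read_dataset.sites.gene == r.gene_id
                            ].itertuples(index=False)
                        )
                        for r in read_dataset.reads
                    ],
                }
            )
            .query("covered")
            .groupby(["gene", "sample", "origin"])
            .size()
        )
        for (gene, sample), row in counted.iterrows():
            assert row.count_R == truth_counts.get((gene, sample, "R"), 0)
            assert row.count_S == truth_counts.get((gene, sample, "S"), 0)
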