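"""Species-diagnostic sites and parental-origin assignment of hybrid reads.

A site is diagnostic when each parental species is fixed for a single
allele there and the two alleles differ. A read is assigned by the
diagnostic bases it covers: unanimous support for one parent assigns it
there, support for both parents is a conflict ("from two parents"), and a
read covering no diagnostic site — or only bases matching neither fixed
allele — is uninformative ("unknown").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .io import sample_from_read_id
from .testing import adjust_pvalues

_VALID_BASES = frozenset("ACGT")

CATEGORIES = ("parent_R", "parent_S", "conflict", "uninformative")


@dataclass
class ReadAssignment:
    read_id: str
    gene_id: str
    n_sites_covered: int
    n_match_R: int
    n_match_S: int
    n_match_neither: int
    category: str


def find_diagnostic_sites(variants_R: pd.DataFrame, variants_S: pd.DataFrame) -> pd.DataFrame:
    """Intersect two per-species consensus tables into diagnostic sites.

    Inputs have columns gene, pos (1-based), alleles ("A" fixed, "A/G"
    polymorphic). A site qualifies only when both species are fixed for a
    single valid base and the bases differ; heterozygous, multiallelic,
    non-ACGT and sites missing from either table are excluded. Output:
    gene, pos, allele_R, allele_S sorted by gene then position.
    """
    for name, table in (("variants_R", variants_R), ("variants_S", variants_S)):
        missing = {"gene", "pos", "alleles"} - set(table.columns)
        if missing:
            raise ValueError(f"{name} lacks columns {sorted(missing)}")
    merged = variants_R.merge(
        variants_S, on=["gene", "pos"], suffixes=("_R", "_S"), how="inner"
    )
    fixed_r = merged["alleles_R"].isin(_VALID_BASES)
    fixed_s = merged["alleles_S"].isin(_VALID_BASES)
    differ = merged["alleles_R"] != merged["alleles_S"]
    out = merged.loc[fixed_r & fixed_s & differ, ["gene", "pos", "alleles_R", "alleles_S"]]
    out = out.rename(columns={"alleles_R": "allele_R", "alleles_S": "allele_S"})
    return out.sort_values(["gene", "pos"]).reset_index(drop=True)


def assign_read(
    read_id: str,
    gene_id: str,
    observed: dict[int, str],
    sites: pd.DataFrame,
) -> ReadAssignment:
    """Assign one read from its observed bases at covered diagnostic sites.

    ``observed`` maps 1-based site position -> base. Bases matching
    neither fixed allele (sequencing errors) are ignored for the verdict:
    matches to both parents make a conflict, matches to exactly one parent
    assign the read, and no informative match leaves it uninformative.
    """
    gene_sites = sites[sites["gene"] == gene_id]
    lookup = {int(r.pos): (r.allele_R, r.allele_S) for r in gene_sites.itertuples(index=False)}
    n_r = n_s = n_neither = n_covered = 0
    for pos, base in observed.items():
        if pos not in lookup:
            continue
        n_covered += 1
        allele_r, allele_s = lookup[pos]
        if base == allele_r:
            n_r += 1
        elif base == allele_s:
            n_s += 1
        else:
            n_neither += 1
    return ReadAssignment(
        read_id=read_id,
        gene_id=gene_id,
        n_sites_covered=n_covered,
        n_match_R=n_r,
        n_match_S=n_s,
        n_match_neither=n_neither,
        category=_categorize(n_covered, n_r, n_s),
    )


def _categorize(n_covered: int, n_r: int, n_s: int) -> str:
    if n_covered == 0 or (n_r == 0 and n_s == 0):
        return "uninformative"
    if n_r > 0 and n_s > 0:
        return "conflict"
    return "parent_R" if n_r > 0 else "parent_S"


def assign_sam(
    sam_path: str | Path,
    sites: pd.DataFrame,
    sample_of: "callable" = sample_from_read_id,
) -> pd.DataFrame:
    """Assign every mapped read in a SAM file.

    Returns one row per read: read_id, sample, gene, n_sites_covered,
    n_match_R, n_match_S, n_match_neither, category. Diagnostic positions
    are converted from 1-based (VCF convention) to 0-based internally.
    """
    by_gene: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for gene, sub in sites.groupby("gene"):
        by_gene[str(gene)] = (
            sub["pos"].to_numpy(dtype=np.int64) - 1,  # 0-based
            sub["allele_R"].to_numpy(dtype=object),
            sub["allele_S"].to_numpy(dtype=object),
        )

    rows: list[tuple] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            gene = aln.reference_name
            n_r = n_s = n_neither = n_covered = 0
            entry = by_gene.get(gene)
            if entry is not None:
                pos0, alleles_r, alleles_s = entry
                start, end = aln.reference_start, aln.reference_end
                seq = aln.query_sequence
                gapless = aln.cigartuples is not None and len(aln.cigartuples) == 1 and aln.cigartuples[0][0] == 0
                if gapless:
                    mask = (pos0 >= start) & (pos0 < end)
                    for p, ar, as_ in zip(pos0[mask], alleles_r[mask], alleles_s[mask]):
                        base = seq[p - start]
                        if base == ar:
                            n_r += 1
                        elif base == as_:
                            n_s += 1
                        else:
                            n_neither += 1
                        n_covered += 1
                else:
                    ref_to_query = {
                        rpos: qpos
                        for qpos, rpos in aln.get_aligned_pairs(matches_only=True)
                    }
                    for p, ar, as_ in zip(pos0, alleles_r, alleles_s):
                        qpos = ref_to_query.get(p)
                        if qpos is None:
                            continue
                        base = seq[qpos]
                        if base == ar:
                            n_r += 1
                        elif base == as_:
                            n_s += 1
                        else:
                            n_neither += 1
                        n_covered += 1
            rows.append(
                (
                    aln.query_name,
                    sample_of(aln.query_name),
                    gene,
                    n_covered,
                    n_r,
                    n_s,
                    n_neither,
                    _categorize(n_covered, n_r, n_s),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "sample",
            "gene",
            "n_sites_covered",
            "n_match_R",
            "n_match_S",
            "n_match_neither",
            "category",
        ],
    )


def count_alleles(
    assignments: pd.DataFrame,
    genes: pd.Index | list[str] | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Tally read categories per gene per sample.

    Returns a frame indexed by (gene, sample) with columns count_R,
    count_S, count_conflict, count_uninformative, count_total. Genes or
    samples given explicitly but absent from the assignments appear as
    all-zero rows; the four categories always sum to the total.
    """
    required = {"sample", "gene", "category"}
    if not required <= set(assignments.columns):
        raise ValueError(f"assignments need columns {sorted(required)}")
    if len(assignments):
        tallies = (
            assignments.groupby(["gene", "sample"])["category"]
            .value_counts()
            .unstack(fill_value=0)
        )
    else:
        tallies = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["gene", "sample"])
        )
    for cat in CATEGORIES:
        if cat not in tallies.columns:
            tallies[cat] = 0
    tallies = tallies[list(CATEGORIES)]
    gene_list = list(genes) if genes is not None else sorted(tallies.index.get_level_values(0).unique())
    sample_list = samples if samples is not None else sorted(tallies.index.get_level_values(1).unique())
    full_index = pd.MultiIndex.from_product([gene_list, sample_list], names=["gene", "sample"])
    tallies = tallies.reindex(full_index, fill_value=0).astype(np.int64)
    out = tallies.rename(
        columns={
            "parent_R": "count_R",
            "parent_S": "count_S",
            "conflict": "count_conflict",
            "uninformative": "count_uninformative",
        }
    )
    out["count_total"] = out.sum(axis=1)
    return out


def assignment_summary(allele_counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample assignment rates and a per-gene parental-bias table.

    Per sample: ``fraction_assigned`` = (R+S)/total and ``bias`` =
    R/(R+S) aggregated over genes (NaN where undefined). Per gene
    (aggregated over samples): the same bias with a two-sided exact
    binomial test of R vs S against 0.5, BH-adjusted.
    """
    per_sample = allele_counts.groupby(level="sample").sum()
    assigned = per_sample["count_R"] + per_sample["count_S"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = assigned / per_sample["count_total"]
        bias = per_sample["count_R"] / assigned
    sample_table = pd.DataFrame(
        {
            "fraction_assigned": frac.where(per_sample["count_total"] > 0),
            "bias": bias.where(assigned > 0),
        }
    )

    per_gene = allele_counts.groupby(level="gene")[["count_R", "count_S"]].sum()
    n_assigned = per_gene["count_R"] + per_gene["count_S"]
    pvals = np.full(len(per_gene), np.nan)
    for i, (r, n) in enumerate(zip(per_gene["count_R"], n_assigned)):
        if n > 0:
            pvals[i] = stats.binomtest(int(r), int(n), 0.5).pvalue
    gene_table = per_gene.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        gene_table["bias"] = np.where(n_assigned > 0, per_gene["count_R"] / n_assigned, np.nan)
    gene_table["p"] = pvals
    gene_table["padj"] = adjust_pvalues(pvals)
    return sample_table, gene_table
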