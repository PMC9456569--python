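"""File formats: counts/design TSV, truth TSV, FASTQ, SAM, VCF.

Writers emit plain text deterministically (stable column and record
order) so that identical inputs give byte-identical files; readers go
through the field-standard libraries (pysam for SAM/VCF, Biopython for
FASTQ) and reconstruct the package's in-memory records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .matrix import CountMatrix
from .simulate import ReadRecord, SimulatedDataset


class CountsParseError(ValueError):
    """Malformed counts table (ragged, non-integer, or duplicated genes)."""


# ---------------------------------------------------------------------------
# counts / design / truth tables


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path, samples: pd.DataFrame | None = None) -> CountMatrix | pd.DataFrame:
    """Read a genes-x-samples TSV; returns a bare frame unless a design is given.

    Raises :class:`CountsParseError` naming the offending cell for
    non-integer values, and for duplicated gene IDs.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise CountsParseError(f"{path}: duplicate gene IDs {dups[:5]}")
    for col in frame.columns:
        values = frame[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric))
        if bad.any():
            gene = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise CountsParseError(
                f"{path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        frame[col] = numeric.astype(np.int64)
    if samples is None:
        return frame
    return CountMatrix(frame, samples)


def write_design(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in design.columns:
        raise ValueError(f"{path}: design table needs a 'group' column")
    return design


def read_count_matrix(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    design = read_design(design_path)
    frame = read_counts(counts_path)
    return CountMatrix(frame[list(design.index)], design)


def write_truth(dataset: SimulatedDataset, path: str | Path) -> None:
    dataset.truth_frame().to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{quality_char * len(read.sequence)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs, via Biopython."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# SAM


def write_sam(
    reads: Sequence[ReadRecord],
    reference_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Ungapped single-end alignments, 1-based POS, full-length match CIGAR."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in sorted(reference_lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{reference_lengths[name]}\n")
        for read in reads:
            qual = "I" * len(read.sequence)
            fh.write(
                f"{read.read_id}\t0\t{read.gene_id}\t{read.start + 1}\t60\t"
                f"{len(read.sequence)}M\t*\t0\t0\t{read.sequence}\t{qual}\n"
            )


def read_sam(path: str | Path) -> tuple[list[ReadRecord], dict[str, int]]:
    """Parse alignments back into records (true origin is not in the file)."""
    records: list[ReadRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            records.append(
                ReadRecord(
                    read_id=aln.query_name,
                    sample=sample_from_read_id(aln.query_name),
                    gene_id=aln.reference_name,
                    start=aln.reference_start,
                    sequence=aln.query_sequence,
                    true_origin="",
                )
            )
    return records, lengths


def sample_from_read_id(read_id: str) -> str:
    """Read IDs are '<sample>:<serial>'."""
    return read_id.rsplit(":", 1)[0]


# ---------------------------------------------------------------------------
# VCF


def write_species_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    species: str,
    sample_name: str | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write one species' consensus at the diagnostic sites as VCF v4.2.

    The reference carries the R allele, so species "R" is written 0/0 and
    species "S" 1/1 at every site. ``sites`` columns: gene, pos (1-based),
    allele_R, allele_S.
    """
    if species not in ("R", "S"):
        raise ValueError("species must be 'R' or 'S'")
    gt = "0/0" if species == "R" else "1/1"
    sample = sample_name or f"pool_{species}"
    ordered = sites.sort_values(["gene", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name in sorted(contig_lengths):
                fh.write(f"##contig=<ID={name},length={contig_lengths[name]}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for row in ordered.itertuples(index=False):
            fh.write(
                f"{row.gene}\t{row.pos}\t.\t{row.allele_R}\t{row.allele_S}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """VCF -> per-site consensus table: gene, pos (1-based), alleles.

    ``alleles`` is the sorted "/"-joined set of bases the species carries
    at the site over all samples in the file (a single base when fixed,
    e.g. "A"; "A/G" when heterozygous or polymorphic).
    """
    rows: list[tuple[str, int, str]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            observed: set[str] = set()
            for sample in rec.samples.values():
                for allele_index in sample["GT"]:
                    if allele_index is None:
                        continue
                    observed.add(rec.alleles[allele_index])
            if not observed:
                continue
            rows.append((rec.chrom, rec.pos, "/".join(sorted(observed))))
    return pd.DataFrame(rows, columns=["gene", "pos", "alleles"])


# ---------------------------------------------------------------------------
# result tables


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
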