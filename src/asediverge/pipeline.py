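"""Orchestration: simulate -> assign -> test -> classify -> stats.

Each stage reads and writes only documented plain-text artifacts inside
the run directory; a manifest with the config hash and SHA-256 checksums
of every artifact is written last, so re-running with an identical config
and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import assign as assign_mod
from . import io as aio
from .classify import classify_dataset, misexpression_proportion, write_summary
from .config import RunConfig
from .stats import compare_categories, divergence_magnitude, run_pca, vst_transform
from .simulate import simulate_dataset
from .testing import run_standard_contrasts

logger = logging.getLogger("asediverge")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on a fresh simulation and return the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    artifacts: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts.append(path)
        return path

    # --- simulate -----------------------------------------------------
    logger.info("[simulate] seed=%d genes=%d", config.seed, config.simulation.n_genes)
    dataset = simulate_dataset(config.simulation, with_reads=config.simulate_reads)
    emit("counts.tsv", lambda p: aio.write_counts(dataset.counts, p))
    emit("design.tsv", lambda p: aio.write_design(dataset.counts.samples, p))
    emit("truth.tsv", lambda p: aio.write_truth(dataset, p))

    # --- assign (read-level, optional) --------------------------------
    if config.simulate_reads:
        logger.info("[assign] seed=%d reads=%d", config.seed, len(dataset.reads))
        lengths = {g: len(seq) for g, seq in dataset.transcripts.items()}
        emit("reads.fastq", lambda p: aio.write_fastq(dataset.reads, p))
        sam_path = emit("alignments.sam", lambda p: aio.write_sam(dataset.reads, lengths, p))
        emit("sites_R.vcf", lambda p: aio.write_species_vcf(dataset.sites, p, "R", contig_lengths=lengths))
        emit("sites_S.vcf", lambda p: aio.write_species_vcf(dataset.sites, p, "S", contig_lengths=lengths))
        tbl_r = aio.read_variant_table(outdir / "sites_R.vcf")
        tbl_s = aio.read_variant_table(outdir / "sites_S.vcf")
        sites = assign_mod.find_diagnostic_sites(tbl_r, tbl_s)
        assignments = assign_mod.assign_sam(sam_path, sites)
        allele_counts = assign_mod.count_alleles(
            assignments, genes=[g.gene_id for g in dataset.truth]
        )
        emit("allele_counts.tsv", lambda p: allele_counts.to_csv(p, sep="\t"))
        sample_summary, gene_bias = assign_mod.assignment_summary(allele_counts)
        emit("assignment_summary.tsv", lambda p: sample_summary.to_csv(p, sep="\t"))
        emit("allelic_bias.tsv", lambda p: gene_bias.to_csv(p, sep="\t"))

    # --- test ----------------------------------------------------------
    logger.info("[test] seed=%d alpha=%g", config.seed, config.testing.alpha)
    contrasts = run_standard_contrasts(dataset.counts, config.testing)
    for key, res in contrasts.as_dict().items():
        emit(f"contrast_{key}.tsv", lambda p, r=res: aio.write_table(r.table, p))

    # --- classify -------------------------------------------------------
    logger.info("[classify] seed=%d", config.seed)
    classifications = classify_dataset(contrasts, config.testing)
    emit("classification.tsv", lambda p: aio.write_table(classifications, p))
    emit("category_proportions.json", lambda p: write_summary(classifications, p))
    mis = misexpression_proportion(classifications)
    emit(
        "misexpression.json",
        lambda p: Path(p).write_text(json.dumps(mis, indent=2) + "\n"),
    )

    # --- stats ----------------------------------------------------------
    logger.info("[stats] seed=%d", config.seed)
    divergence = divergence_magnitude(contrasts.P, classifications)
    emit("divergence.tsv", lambda p: aio.write_table(divergence, p))
    try:
        comparisons = compare_categories(divergence)
        emit("category_comparisons.tsv", lambda p: comparisons.to_csv(p, sep="\t", index=False))
    except ValueError as exc:
        logger.warning("[stats] category comparison skipped: %s", exc)
    vst = vst_transform(dataset.counts.data, contrasts.size_factors)
    pca = run_pca(vst)
    emit("pca_scores.tsv", lambda p: aio.write_table(pca.scores, p))
    emit("pca_loadings.tsv", lambda p: aio.write_table(pca.loadings, p))

    manifest = {
        "config_hash": hashlib.sha256(config.config_hash_payload().encode()).hexdigest(),
        "seed": config.seed,
        "stages": {
            "simulate": True,
            "assign": bool(config.simulate_reads),
            "test": True,
            "classify": True,
            "stats": True,
        },
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "version": _package_version(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__


def require_inputs(paths: list[str | Path]) -> None:
    """Validate that every referenced input exists before running a stage."""
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineError(f"missing input file(s): {', '.join(missing)}")


def deterministic_manifest_fields(manifest: dict) -> dict:
    """The manifest minus volatile fields (timestamps)."""
    return {k: v for k, v in manifest.items() if k != "timestamp"}
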