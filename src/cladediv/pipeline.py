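"""End-to-end orchestration: clades -> markers -> profile -> variants -> indices.

``analyze_cohort`` is the in-memory engine; ``run_pipeline`` wires it to the
on-disk formats and writes a versioned run manifest (config, input checksums,
global floor) so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .clades import CladePartition, consensus_partition, ward_cluster
from .config import RunConfig
from .indices import (
    GlobalFloor,
    HousekeepingBaseline,
    aggregate_global,
    aggregate_population,
    compute_global_floor,
    filter_diverging_markers,
    housekeeping_baseline,
    sample_indices,
    stats_to_frame,
    validate_baselines,
)
from .markers import MarkerCatalog, build_catalog
from .pangenome import jaccard_distance, load_ani_matrix
from .profiling import CohortMetadata, MarkerCoverage, calls_to_frame, profile_sample
from .variants import VariantRecord, build_consensus, filter_variants, gene_variant_stats, tajimas_d

from . import io as cio

logger = logging.getLogger("cladediv")


@dataclass
class AnalysisResult:
    calls: pd.DataFrame
    cohort_summary: dict
    stats: pd.DataFrame
    baselines: list[HousekeepingBaseline]
    floor: GlobalFloor
    index_table: pd.DataFrame
    global_table: pd.DataFrame
    population_table: pd.DataFrame
    diverging: pd.DataFrame
    tajima: pd.DataFrame
    baseline_validation: pd.DataFrame
    gated_samples: list[str] = field(default_factory=list)


def _observed_genes(cov: MarkerCoverage, catalog: MarkerCatalog, min_cov: float) -> list[str]:
    return sorted(
        g for g, d in cov.depths.items()
        if d >= min_cov and g in catalog.sequences
    )


def compute_sample_stats(
    cov: MarkerCoverage,
    variants: dict[str, list[VariantRecord]],
    catalog: MarkerCatalog,
    cfg: RunConfig,
) -> tuple[list, dict[str, str]]:
    """Per-gene variant statistics and consensus sequences for one sample.

    Genes are considered observed when their mean depth reaches the marker
    presence threshold; genes without variant records get zero SNP counts.
    """
    stats = []
    consensus: dict[str, str] = {}
    for gene in _observed_genes(cov, catalog, cfg.min_marker_cov):
        recs = variants.get(gene, [])
        ref = catalog.sequences[gene]
        s = gene_variant_stats(
            cov.sample_id, gene, recs, ref,
            min_depth=cfg.min_depth, min_qual=cfg.min_qual,
            ds_min=cfg.ds_min, ds_max=cfg.ds_max,
        )
        stats.append(s)
        filtered = filter_variants(recs, cfg.min_depth, cfg.min_qual)
        consensus[gene] = build_consensus(ref, filtered)
    return stats, consensus


def tajima_table(
    consensus_by_sample: dict[str, dict[str, str]],
    calls: pd.DataFrame,
    catalog: MarkerCatalog,
) -> pd.DataFrame:
    """Tajima's D per (clade, gene, mask) over across-sample consensus sets.

    For each clade, the haplotype set of a gene is the consensus sequence of
    every gated sample in which the clade was called present (n >= 3
    required).  Markers are evaluated within their own clade; core genes are
    evaluated within every clade.
    """
    present_samples = {
        clade: sorted(sub.loc[sub["present"], "sample_id"])
        for clade, sub in calls.groupby("clade")
    }
    rows = []

    def eval_gene(clade: str, gene: str) -> None:
        samples = [
            s for s in present_samples.get(clade, [])
            if s in consensus_by_sample and gene in consensus_by_sample[s]
        ]
        if len(samples) < 3:
            return
        seqs = [consensus_by_sample[s][gene] for s in samples]
        ref = catalog.sequences[gene]
        for mask in ("all", "synonymous"):
            res = tajimas_d(seqs, synonymous=(mask == "synonymous"), ref_seq=ref)
            rows.append((clade, gene, catalog.role_of(gene), mask,
                         res.n, res.S, res.pi, res.D if res.defined else float("nan")))

    for clade in catalog.clades:
        for gene in catalog.markers[clade]:
            eval_gene(clade, gene)
        for gene in catalog.core:
            eval_gene(clade, gene)
    return pd.DataFrame(
        rows, columns=["clade", "gene_id", "role", "mask", "n", "S", "pi", "D"]
    )


def analyze_cohort(
    catalog: MarkerCatalog,
    coverages: list[MarkerCoverage],
    variants: dict[str, dict[str, list[VariantRecord]]],
    metadata: CohortMetadata,
    cfg: RunConfig | None = None,
    compute_tajima: bool = True,
) -> AnalysisResult:
    """Run profiling, variant statistics and divergence indices over a cohort."""
    cfg = cfg or RunConfig()
    all_calls = []
    for cov in coverages:
        all_calls.extend(
            profile_sample(cov, catalog, cfg.clade_fraction, cfg.min_marker_cov,
                           cfg.genome_size_bp)
        )
    calls = calls_to_frame(all_calls)
    summary = _safe_summary(calls, metadata)

    # species-level gate: variant analysis only for samples rich enough in
    # the target species; everything stays in the prevalence summaries
    gated = [
        cov for cov in coverages
        if cov.species_relative_abundance is None
        or cov.species_relative_abundance >= cfg.species_gate
    ]
    gated_ids = [c.sample_id for c in gated]
    logger.info("samples passing species gate: %d / %d", len(gated), len(coverages))

    stats_records = []
    consensus_by_sample: dict[str, dict[str, str]] = {}
    for cov in gated:
        s, cons = compute_sample_stats(cov, variants.get(cov.sample_id, {}), catalog, cfg)
        stats_records.extend(s)
        consensus_by_sample[cov.sample_id] = cons
    stats = stats_to_frame(stats_records)

    baselines = []
    for cov in gated:
        try:
            baselines.append(housekeeping_baseline(stats, catalog, cov.sample_id))
        except ValueError:
            logger.warning("sample %s: no housekeeping statistics; skipped", cov.sample_id)
    floor = compute_global_floor(baselines)

    index_parts = [
        sample_indices(stats, bl, catalog, floor) for bl in baselines
    ]
    index_table = (
        pd.concat(index_parts, ignore_index=True)
        if index_parts
        else pd.DataFrame(columns=["sample_id", "level", "key", "clade",
                                   "DRI", "DRI_flag", "NDRI", "NDRI_flag"])
    )
    global_table = aggregate_global(index_table) if len(index_table) else pd.DataFrame()
    population_table = (
        aggregate_population(index_table, metadata) if len(index_table) else pd.DataFrame()
    )
    diverging = (
        filter_diverging_markers(global_table) if len(global_table) else pd.DataFrame()
    )

    gated_calls = calls[calls["sample_id"].isin(gated_ids)]
    tajima = (
        tajima_table(consensus_by_sample, gated_calls, catalog)
        if compute_tajima
        else pd.DataFrame()
    )

    manifest = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in gated],
            "metagenome_size_bp": [c.metagenome_size_bp for c in gated],
            "species_relative_abundance": [
                c.species_relative_abundance for c in gated
            ],
        }
    )
    validation = (
        validate_baselines(baselines, manifest, global_table, catalog.prevalence)
        if len(baselines) >= 3
        else pd.DataFrame()
    )

    return AnalysisResult(
        calls=calls,
        cohort_summary=summary,
        stats=stats,
        baselines=baselines,
        floor=floor,
        index_table=index_table,
        global_table=global_table,
        population_table=population_table,
        diverging=diverging,
        tajima=tajima,
        baseline_validation=validation,
        gated_samples=gated_ids,
    )


def _safe_summary(calls: pd.DataFrame, metadata: CohortMetadata) -> dict:
    from .profiling import summarize_cohort

    summary = summarize_cohort(calls, metadata)
    # pairwise tables are DataFrames; keep the dict JSON-serializable
    summary["pairwise"] = {
        facet: df.to_dict(orient="records") for facet, df in summary["pairwise"].items()
    }
    return summary


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_partition(input_dir: str, cfg: RunConfig) -> CladePartition:
    """Clade definition stage: Ward clustering of the Jaccard matrix, combined
    with the ANI-based partition via the partition meet when an ANI table is
    present."""
    from .pangenome import read_presence_absence

    pam = read_presence_absence(os.path.join(input_dir, "gene_presence_absence.csv"))
    dm_j = jaccard_distance(pam)
    p_j = ward_cluster(dm_j, cfg.k_clades, cfg.ward_variant)
    ani_path = os.path.join(input_dir, "ani_pairs.tsv")
    if os.path.exists(ani_path):
        dm_a = load_ani_matrix(cio.read_ani_pairs(ani_path), cfg.min_ani_alignment_bp)
        p_a = ward_cluster(dm_a, cfg.k_clades, cfg.ward_variant)
        return consensus_partition(p_j, p_a)
    return p_j


def run_pipeline(input_dir: str, out_dir: str, cfg: RunConfig | None = None) -> dict:
    """Execute the full analysis from an input directory of the documented
    formats and write every output table plus the run manifest."""
    cfg = cfg or RunConfig()
    os.makedirs(out_dir, exist_ok=True)
    from .pangenome import read_presence_absence

    pam_path = os.path.join(input_dir, "gene_presence_absence.csv")
    pam = read_presence_absence(pam_path)

    partition_path = os.path.join(input_dir, "partition.tsv")
    if os.path.exists(partition_path):
        partition = CladePartition.from_frame(pd.read_csv(partition_path, sep="\t"))
        logger.info("using precomputed partition (%d clades)", len(partition.labels))
    else:
        partition = derive_partition(input_dir, cfg)
    partition.to_frame().to_csv(os.path.join(out_dir, "partition.tsv"), sep="\t", index=False)

    fasta_path = os.path.join(input_dir, "catalog.fasta")
    manifest_path = os.path.join(input_dir, "catalog.tsv")
    if os.path.exists(fasta_path) and os.path.exists(manifest_path):
        catalog = cio.read_catalog_fasta(fasta_path, manifest_path)
    else:
        sequences = _load_panel_sequences(input_dir)
        catalog = build_catalog(
            pam, partition, sequences=sequences,
            presence_fraction=cfg.marker_presence,
            core_fraction=cfg.core_fraction, n_core=cfg.n_core, seed=cfg.seed,
        )
    cio.write_catalog_fasta(
        catalog,
        os.path.join(out_dir, "catalog.fasta"),
        os.path.join(out_dir, "catalog.tsv"),
    )
    for clade in catalog.clades:
        logger.info("clade %s: %d marker genes", clade, len(catalog.markers[clade]))

    coverages = cio.read_coverage(
        os.path.join(input_dir, "coverage.tsv"),
        os.path.join(input_dir, "manifest.tsv"),
    )
    metadata = cio.read_metadata(os.path.join(input_dir, "metadata.tsv"))
    variants = {}
    vcf_dir = os.path.join(input_dir, "vcf")
    if os.path.isdir(vcf_dir):
        for cov in coverages:
            path = os.path.join(vcf_dir, f"{cov.sample_id}.vcf")
            if os.path.exists(path):
                per_gene: dict[str, list[VariantRecord]] = {}
                for rec in cio.read_vcf(path):
                    per_gene.setdefault(rec.gene_id, []).append(rec)
                variants[cov.sample_id] = per_gene

    result = analyze_cohort(catalog, coverages, variants, metadata, cfg)

    result.calls.to_csv(os.path.join(out_dir, "clade_calls.tsv"), sep="\t", index=False)
    result.stats.to_csv(os.path.join(out_dir, "gene_stats.tsv"), sep="\t", index=False)
    result.index_table.to_csv(os.path.join(out_dir, "indices.tsv"), sep="\t", index=False)
    result.global_table.to_csv(os.path.join(out_dir, "aggregates_global.tsv"), sep="\t", index=False)
    result.population_table.to_csv(
        os.path.join(out_dir, "aggregates_population.tsv"), sep="\t", index=False
    )
    result.diverging.to_csv(os.path.join(out_dir, "diverging_markers.tsv"), sep="\t", index=False)
    result.tajima.to_csv(os.path.join(out_dir, "tajima.tsv"), sep="\t", index=False)
    result.baseline_validation.to_csv(
        os.path.join(out_dir, "baseline_validation.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "cohort_summary.json"), "w") as fh:
        json.dump(result.cohort_summary, fh, indent=1, sort_keys=True)

    inputs = sorted(
        os.path.join(root, f)
        for root, _, files in os.walk(input_dir)
        for f in files
    )
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "global_floor": {"min_MH": result.floor.min_MH, "min_muH": result.floor.min_muH},
        "n_samples": len(coverages),
        "n_samples_gated": len(result.gated_samples),
        "input_checksums": {os.path.relpath(p, input_dir): _checksum(p) for p in inputs},
    }
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _load_panel_sequences(input_dir: str) -> dict[str, dict[str, str]]:
    """Per-genome FASTA files panel/<genome>.fasta with one record per gene."""
    from Bio import SeqIO

    panel_dir = os.path.join(input_dir, "panel")
    sequences: dict[str, dict[str, str]] = {}
    if not os.path.isdir(panel_dir):
        return sequences
    for name in sorted(os.listdir(panel_dir)):
        if not name.endswith(".fasta"):
            continue
        genome = name[: -len(".fasta")]
        for rec in SeqIO.parse(os.path.join(panel_dir, name), "fasta"):
            sequences.setdefault(rec.id, {})[genome] = str(rec.seq)
    return sequences


def write_cohort(cohort, out_dir: str) -> None:
    """Materialize a synthetic cohort in the pipeline's input formats."""
    os.makedirs(out_dir, exist_ok=True)
    cio.write_roary_csv(cohort.panel.pam, os.path.join(out_dir, "gene_presence_absence.csv"))
    cohort.panel.ani_pairs.to_csv(os.path.join(out_dir, "ani_pairs.tsv"), sep="\t", index=False)
    panel_dir = os.path.join(out_dir, "panel")
    os.makedirs(panel_dir, exist_ok=True)
    by_genome: dict[str, list[tuple[str, str]]] = {}
    for gene, per_genome in cohort.panel.sequences.items():
        for genome, seq in per_genome.items():
            by_genome.setdefault(genome, []).append((gene, seq))
    for genome, entries in sorted(by_genome.items()):
        with open(os.path.join(panel_dir, f"{genome}.fasta"), "w") as fh:
            for gene, seq in sorted(entries):
                fh.write(f">{gene}\n{seq}\n")
    cohort.panel.partition.to_frame().to_csv(
        os.path.join(out_dir, "partition_truth.tsv"), sep="\t", index=False
    )
    cio.write_coverage(
        [s.coverage for s in cohort.samples],
        os.path.join(out_dir, "coverage.tsv"),
        os.path.join(out_dir, "manifest.tsv"),
    )
    vcf_dir = os.path.join(out_dir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    for s in cohort.samples:
        records = [r for recs in s.variants.values() for r in recs]
        contigs = {g: len(cohort.catalog.sequences[g])
                   for g in s.variants if g in cohort.catalog.sequences}
        cio.write_vcf(records, contigs, os.path.join(vcf_dir, f"{s.sample_id}.vcf"), s.sample_id)
    meta = cohort.metadata.df.reset_index()
    meta.columns = ["sample_id", "population", "lifestyle", "age_group"]
    meta.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)
    cio.write_truth(cohort.truth.to_dict(), os.path.join(out_dir, "truth.json"))
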