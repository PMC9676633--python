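"""Readers and writers for the pipeline's on-disk formats.

Formats: ROARY-style presence/absence CSV, labeled square distance-matrix
CSV, long-format ANI TSV, per-sample per-gene coverage TSV + sample manifest
TSV, VCF v4.2 (CHROM = gene id, haploid SNVs), multi-FASTA catalogs, sample
metadata TSV and the synthetic-truth JSON.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .markers import MarkerCatalog
from .pangenome import DistanceMatrix, PresenceAbsenceMatrix
from .profiling import CohortMetadata, MarkerCoverage
from .variants import VariantRecord

__all__ = [
    "write_roary_csv",
    "write_distance_csv",
    "read_distance_csv",
    "read_ani_pairs",
    "write_coverage",
    "read_coverage",
    "write_vcf",
    "read_vcf",
    "write_catalog_fasta",
    "read_catalog_fasta",
    "write_truth",
    "read_metadata",
]

_ROARY_HEADER = [
    "Gene", "Non-unique Gene name", "Annotation", "No. isolates", "No. sequences",
    "Avg sequences per isolate", "Genome Fragment", "Order within Fragment",
    "Accessory Fragment", "Accessory Order with Fragment", "QC",
    "Min group size nuc", "Max group size nuc", "Avg group size nuc",
]


def write_roary_csv(pam: PresenceAbsenceMatrix, path: str) -> None:
    """Write the quoted ROARY gene_presence_absence.csv dialect."""
    genomes = pam.genome_ids
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(_ROARY_HEADER + genomes)
        for gene in pam.gene_ids:
            present = pam.df[gene]
            n = int(present.sum())
            meta = [gene, pam.gene_names.get(gene, ""), "", str(n), str(n),
                    "1", "", "", "", "", "", "", "", ""]
            cells = [genome if present[genome] else "" for genome in genomes]
            writer.writerow(meta + cells)


def write_distance_csv(dm: DistanceMatrix, path: str) -> None:
    dm.to_frame().to_csv(path, index_label="")


def read_distance_csv(path: str, metric_tag: str = "other") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix.from_frame(df, metric_tag)


def read_ani_pairs(path: str) -> pd.DataFrame:
    """Long-format ANI TSV: id_i, id_j, identity, aln_length."""
    return pd.read_csv(path, sep="\t")


def write_coverage(covs: Iterable[MarkerCoverage], cov_path: str, manifest_path: str) -> None:
    rows = []
    manifest = []
    for cov in covs:
        for gene, depth in sorted(cov.depths.items()):
            rows.append((cov.sample_id, gene, depth))
        manifest.append(
            (cov.sample_id, cov.metagenome_size_bp, cov.species_relative_abundance)
        )
    pd.DataFrame(rows, columns=["sample_id", "gene_id", "mean_depth"]).to_csv(
        cov_path, sep="\t", index=False
    )
    pd.DataFrame(
        manifest,
        columns=["sample_id", "metagenome_size_bp", "species_relative_abundance"],
    ).to_csv(manifest_path, sep="\t", index=False)


def read_coverage(cov_path: str, manifest_path: str) -> list[MarkerCoverage]:
    cov = pd.read_csv(cov_path, sep="\t")
    manifest = pd.read_csv(manifest_path, sep="\t").set_index("sample_id")
    out = []
    grouped = {sid: dict(zip(sub["gene_id"], sub["mean_depth"]))
               for sid, sub in cov.groupby("sample_id")}
    for sid, row in manifest.iterrows():
        sra = row.get("species_relative_abundance")
        out.append(
            MarkerCoverage(
                sample_id=str(sid),
                depths=grouped.get(str(sid), {}),
                metagenome_size_bp=int(row["metagenome_size_bp"]),
                species_relative_abundance=None if pd.isna(sra) else float(sra),
            )
        )
    return out


def write_vcf(
    records: Iterable[VariantRecord],
    contig_lengths: dict[str, int],
    path: str,
    sample_id: str = "sample",
) -> None:
    """Write haploid SNVs as VCF v4.2 with CHROM = gene id and INFO/DP."""
    recs = sorted(records, key=lambda r: (r.gene_id, r.position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cladediv\n")
        for contig in sorted({r.gene_id for r in recs} | set(contig_lengths)):
            length = contig_lengths.get(contig, 0)
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
        )
        for r in recs:
            fh.write(
                f"{r.gene_id}\t{r.position}\t.\t{r.ref}\t{r.alt}\t{r.qual:.2f}\t.\t"
                f"DP={r.depth}\tGT\t1\n"
            )


def read_vcf(path: str) -> list[VariantRecord]:
    """Read haploid SNVs; multi-allelic records are split, indels rejected."""
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    vcf = VCF(path)
    try:
        for v in vcf:
            depth = v.INFO.get("DP")
            depth = int(depth) if depth is not None else 0
            qual = float(v.QUAL) if v.QUAL is not None else 0.0
            for alt in v.ALT:
                if len(v.REF) != 1 or len(alt) != 1:
                    raise ValueError(
                        f"{path}: {v.CHROM}:{v.POS}: indel records are out of scope "
                        f"(REF={v.REF}, ALT={alt})"
                    )
                out.append(
                    VariantRecord(
                        gene_id=v.CHROM,
                        position=int(v.POS),
                        ref=v.REF,
                        alt=alt,
                        depth=depth,
                        qual=qual,
                    )
                )
    finally:
        vcf.close()
    return out


def write_catalog_fasta(catalog: MarkerCatalog, fasta_path: str, manifest_path: str) -> None:
    """Multi-FASTA of representative sequences, headers gene_id|clade|role."""
    records = []
    clade_of = catalog.clade_of_marker
    for gene, seq in sorted(catalog.sequences.items()):
        role = catalog.role_of(gene)
        clade = clade_of.get(gene, "")
        records.append(
            SeqRecord(Seq(seq), id=f"{gene}|{clade}|{role}", description="")
        )
    SeqIO.write(records, fasta_path, "fasta")
    catalog.to_manifest().to_csv(manifest_path, sep="\t", index=False)


def read_catalog_fasta(fasta_path: str, manifest_path: str) -> MarkerCatalog:
    manifest = pd.read_csv(manifest_path, sep="\t", keep_default_na=False)
    sequences = {}
    for rec in SeqIO.parse(fasta_path, "fasta"):
        gene = rec.id.split("|")[0]
        sequences[gene] = str(rec.seq)
    markers: dict[str, list[str]] = {}
    housekeeping: list[str] = []
    core: list[str] = []
    prevalence: dict[str, float] = {}
    for row in manifest.itertuples(index=False):
        if row.role == "marker":
            markers.setdefault(row.clade, []).append(row.gene_id)
            prevalence[row.gene_id] = float(row.prevalence_in_clade)
        elif row.role == "housekeeping":
            housekeeping.append(row.gene_id)
        elif row.role == "core":
            core.append(row.gene_id)
    return MarkerCatalog(
        markers=markers,
        housekeeping=housekeeping,
        core=core,
        sequences=sequences,
        prevalence=prevalence,
    )


def write_truth(truth_dict: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)


def read_metadata(path: str) -> CohortMetadata:
    return CohortMetadata.from_frame(pd.read_csv(path, sep="\t"))


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
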