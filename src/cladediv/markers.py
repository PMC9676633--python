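"""Clade-specific marker genes, core genes and the housekeeping baseline panel.

A gene is a marker for a clade when it is present in at least 95% (default)
of that clade's genomes and completely absent from every genome of every
other clade.  Core genes are present in >=95% of the whole panel; a random
subset of them (default 500) serves as the neutral control.  Ten essential
genes present in all panel genomes (recA, rplS, rplI, purN, mreB, maf, fmt,
gyrB, rpoB, proC) form the housekeeping baseline against which divergence
indices are normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clades import CladePartition
from .pangenome import PresenceAbsenceMatrix

__all__ = [
    "HOUSEKEEPING_GENE_NAMES",
    "MarkerCatalog",
    "identify_markers",
    "identify_core_genes",
    "select_housekeeping",
    "build_catalog",
]

HOUSEKEEPING_GENE_NAMES: tuple[str, ...] = (
    "recA", "rplS", "rplI", "purN", "mreB", "maf", "fmt", "gyrB", "rpoB", "proC",
)

# gene_id -> {genome_id -> nucleotide sequence}
SequenceStore = Mapping[str, Mapping[str, str]]


@dataclass
class MarkerCatalog:
    """Per-clade marker sets plus housekeeping and core panels.

    ``sequences`` maps gene_id to its representative nucleotide sequence
    (by default the copy from the lexicographically smallest genome carrying
    the gene, so catalogs are reproducible).
    """

    markers: dict[str, list[str]]
    housekeeping: list[str]
    core: list[str]
    sequences: dict[str, str] = field(default_factory=dict)
    presence_fraction: float = 0.95
    core_fraction: float = 0.95
    prevalence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for clade, genes in self.markers.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"marker {g} assigned to both {seen[g]} and {clade}"
                    )
                seen[g] = clade

    @property
    def clade_of_marker(self) -> dict[str, str]:
        return {g: c for c, genes in self.markers.items() for g in genes}

    @property
    def clades(self) -> list[str]:
        return sorted(self.markers)

    def gene_length(self, gene_id: str) -> int:
        return len(self.sequences[gene_id])

    def role_of(self, gene_id: str) -> str:
        if gene_id in self.clade_of_marker:
            return "marker"
        if gene_id in self.housekeeping:
            return "housekeeping"
        if gene_id in self.core:
            return "core"
        return "other"

    def to_manifest(self) -> pd.DataFrame:
        rows = []
        for clade in self.clades:
            for g in self.markers[clade]:
                rows.append((g, clade, "marker", self._len(g), self.prevalence.get(g, np.nan)))
        for g in self.housekeeping:
            rows.append((g, "", "housekeeping", self._len(g), 1.0))
        for g in self.core:
            rows.append((g, "", "core", self._len(g), self.prevalence.get(g, np.nan)))
        return pd.DataFrame(
            rows, columns=["gene_id", "clade", "role", "length_bp", "prevalence_in_clade"]
        )

    def _len(self, g: str) -> float:
        return len(self.sequences[g]) if g in self.sequences else np.nan


def _representative(gene_id: str, seqs: SequenceStore | None) -> str | None:
    if seqs is None or gene_id not in seqs or not seqs[gene_id]:
        return None
    genome = min(seqs[gene_id])
    return seqs[gene_id][genome]


def identify_markers(
    pam: PresenceAbsenceMatrix,
    partition: CladePartition,
    presence_fraction: float = 0.95,
    sequences: SequenceStore | None = None,
) -> tuple[dict[str, list[str]], dict[str, float]]:
    """Identify clade-specific markers.

    Returns (markers by clade, per-marker within-clade prevalence).  A gene is
    a marker for clade c iff its presence fraction within c is >= the
    threshold (inclusive) and it is absent from every genome of every other
    clade.  Outgroup genomes are ignored entirely.
    """
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must lie in (0, 1]")
    clades = partition.clades
    for clade, members in clades.items():
        if not members:
            raise ValueError(f"clade {clade} has no genomes")
        missing = set(members) - set(pam.genome_ids)
        if missing:
            raise ValueError(f"clade {clade} genomes absent from matrix: {sorted(missing)}")
    sub = pam.df.loc[[g for members in clades.values() for g in members]]
    frac = pd.DataFrame(
        {clade: sub.loc[members].mean(axis=0) for clade, members in clades.items()}
    )  # genes x clades
    markers: dict[str, list[str]] = {c: [] for c in clades}
    prevalence: dict[str, float] = {}
    for clade in clades:
        others = [c for c in clades if c != clade]
        ok = (frac[clade] >= presence_fraction) & (frac[others] == 0).all(axis=1)
        for gene in frac.index[ok]:
            markers[clade].append(gene)
            prevalence[gene] = float(frac.at[gene, clade])
    return markers, prevalence


def identify_core_genes(
    pam: PresenceAbsenceMatrix,
    core_fraction: float = 0.95,
    n_select: int = 500,
    seed: int = 0,
    exclude: set[str] | None = None,
) -> list[str]:
    """Uniform random sample (without replacement) of panel core genes.

    Core genes are present in at least ``core_fraction`` of all panel genomes;
    the sample is reproducible under ``seed`` and clamped with a warning when
    fewer than ``n_select`` genes are eligible.  ``exclude`` removes genes
    (e.g. the housekeeping panel) from eligibility before sampling.
    """
    frac = pam.df.mean(axis=0)
    eligible = sorted(set(frac.index[frac >= core_fraction]) - (exclude or set()))
    if not eligible:
        raise ValueError("no genes reach the core presence fraction")
    if len(eligible) <= n_select:
        if len(eligible) < n_select:
            warnings.warn(
                f"only {len(eligible)} core-eligible genes; requested {n_select}",
                stacklevel=2,
            )
        return eligible
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_select, replace=False)
    return sorted(eligible[i] for i in chosen)


def select_housekeeping(
    pam: PresenceAbsenceMatrix,
    names: tuple[str, ...] = HOUSEKEEPING_GENE_NAMES,
) -> list[str]:
    """Resolve housekeeping gene names to gene ids and verify universality.

    Resolution is an exact case-insensitive match on the pangenome gene-name
    annotation; every resolved gene must be present in 100% of panel genomes.
    """
    if not names:
        raise ValueError("housekeeping gene name list is empty")
    lowered: dict[str, list[str]] = {}
    for gid, name in pam.gene_names.items():
        lowered.setdefault(name.lower(), []).append(gid)
    # ROARY names single-copy clusters by their annotated gene name, so the
    # cluster id itself resolves when no separate annotation is available
    for gid in pam.gene_ids:
        if gid not in pam.gene_names:
            lowered.setdefault(gid.lower(), []).append(gid)
    resolved: list[str] = []
    problems: list[str] = []
    for name in names:
        hits = lowered.get(name.lower(), [])
        if not hits:
            problems.append(f"{name}: not found")
        elif len(hits) > 1:
            problems.append(f"{name}: ambiguous ({', '.join(sorted(hits))})")
        else:
            resolved.append(hits[0])
    if problems:
        raise ValueError("housekeeping resolution failed: " + "; ".join(problems))
    not_universal = [
        name for name, gid in zip(names, resolved) if pam.df[gid].mean() < 1.0
    ]
    if not_universal:
        raise ValueError(
            "housekeeping genes not present in all genomes: " + ", ".join(not_universal)
        )
    return resolved


def build_catalog(
    pam: PresenceAbsenceMatrix,
    partition: CladePartition,
    sequences: SequenceStore | None = None,
    presence_fraction: float = 0.95,
    core_fraction: float = 0.95,
    n_core: int = 500,
    housekeeping_names: tuple[str, ...] = HOUSEKEEPING_GENE_NAMES,
    seed: int = 0,
) -> MarkerCatalog:
    """Assemble the full catalog: markers, housekeeping panel and core sample."""
    markers, prevalence = identify_markers(pam, partition, presence_fraction, sequences)
    housekeeping = select_housekeeping(pam, housekeeping_names)
    core = identify_core_genes(pam, core_fraction, n_core, seed, exclude=set(housekeeping))
    catalog_genes = set(housekeeping) | set(core)
    catalog_genes.update(g for genes in markers.values() for g in genes)
    seqs: dict[str, str] = {}
    if sequences is not None:
        for g in catalog_genes:
            rep = _representative(g, sequences)
            if rep is not None:
                seqs[g] = rep
    return MarkerCatalog(
        markers=markers,
        housekeeping=housekeeping,
        core=core,
        sequences=seqs,
        presence_fraction=presence_fraction,
        core_fraction=core_fraction,
        prevalence=prevalence,
    )
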