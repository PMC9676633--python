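"""Synthetic-cohort generator with planted ground truth.

Emulates the study design end to end at desk scale: a panel of genomes
partitioned into clades, per-clade marker genes (present in every genome of
their clade, absent elsewhere), a universal housekeeping panel, panel-wide
core genes, per-genome private accessory genes (so gene-content distances
separate clades without collapsing within-clade diversity), a synthetic ANI
table, and per-sample marker coverage plus injected SNVs at controlled
per-base rates and controlled synonymous/non-synonymous ratios.

Everything is driven by one seed through hierarchically derived random
streams (panel, then per sample, then per gene), so adding samples never
perturbs earlier samples and identical configs regenerate identical data.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clades import CladePartition, clade_labels
from .markers import HOUSEKEEPING_GENE_NAMES, MarkerCatalog, build_catalog
from .pangenome import PresenceAbsenceMatrix
from .profiling import CohortMetadata, MarkerCoverage
from .variants import BASES, VariantRecord, classify_sites, translate_codon

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticPanel",
    "SyntheticCohort",
    "simulate_panel",
    "mutate_codon_sequence",
    "simulate_sample",
    "simulate_cohort",
]

_SENSE_CODONS = sorted(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if translate_codon(a + b + c) != "*"
)

_DEFAULT_POPULATIONS = (
    ("Germany", "industrial-urban"),
    ("Italy", "industrial-urban"),
    ("NorthAmerica", "industrial-urban"),
    ("Peru-rural", "rural"),
    ("Tanzania-HG", "hunter-gatherer"),
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study design: 5 clades, marker genes mutating
    e times faster than the housekeeping baseline (so the planted log-ratio
    divergence is exactly 1), core genes at the baseline rate, purifying
    omega on housekeeping/core genes and elevated omega on markers.
    """

    n_clades: int = 5
    genomes_per_clade: int = 10
    markers_per_clade: int = 12
    n_core_genes: int = 60
    n_housekeeping: int = 10
    accessory_per_genome: int = 8
    gene_length_bp: int = 900
    hk_rate: float = 0.01                     # per-bp SNP rate, housekeeping baseline
    core_rate_multiplier: float = 1.0
    marker_rate_multiplier: float | tuple[float, ...] = math.e
    target_omega_hk: float = 0.2
    target_omega_core: float = 0.2
    target_omega_marker: float = 0.4
    coverage_mean: float = 5.0                # X over genes of a present clade
    clade_presence_prob: float = 0.8
    n_samples: int = 50
    populations: tuple[tuple[str, str], ...] = _DEFAULT_POPULATIONS
    metagenome_size_bp: int = 2_000_000_000
    genome_size_bp: int = 3_000_000
    filter_fail_fraction: float = 0.0         # planted filter-failing records
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clades", "genomes_per_clade", "markers_per_clade",
                     "n_housekeeping", "n_samples", "gene_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.gene_length_bp % 3 != 0:
            raise ValueError("gene_length_bp must be a multiple of 3")
        rates = [self.hk_rate,
                 self.hk_rate * self.core_rate_multiplier,
                 *[self.hk_rate * m for m in self.marker_multipliers]]
        if any(not 0 <= r <= 0.5 for r in rates):
            raise ValueError("per-bp SNP rates must lie in [0, 0.5]")
        for om in (self.target_omega_hk, self.target_omega_core, self.target_omega_marker):
            if om < 0:
                raise ValueError("target omega must be >= 0")

    @property
    def marker_multipliers(self) -> tuple[float, ...]:
        if isinstance(self.marker_rate_multiplier, (int, float)):
            return tuple([float(self.marker_rate_multiplier)] * self.n_clades)
        if len(self.marker_rate_multiplier) != self.n_clades:
            raise ValueError("need one marker rate multiplier per clade")
        return tuple(float(m) for m in self.marker_rate_multiplier)

    @property
    def clade_names(self) -> list[str]:
        return clade_labels(self.n_clades)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every generated dataset."""

    partition: dict[str, str]
    markers: dict[str, list[str]]
    housekeeping: list[str]
    core: list[str]
    gene_rates: dict[str, float]
    gene_omegas: dict[str, float]
    samples: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "markers": self.markers,
            "housekeeping": self.housekeeping,
            "core": self.core,
            "gene_rates": self.gene_rates,
            "gene_omegas": self.gene_omegas,
            "samples": self.samples,
        }


@dataclass
class SyntheticPanel:
    pam: PresenceAbsenceMatrix
    sequences: dict[str, dict[str, str]]  # gene -> genome -> sequence
    ani_pairs: pd.DataFrame
    partition: CladePartition
    truth: SyntheticTruth


@dataclass
class SyntheticSample:
    sample_id: str
    coverage: MarkerCoverage
    variants: dict[str, list[VariantRecord]]  # gene -> records


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    panel: SyntheticPanel
    catalog: MarkerCatalog
    samples: list[SyntheticSample]
    manifest: pd.DataFrame
    metadata: CohortMetadata
    truth: SyntheticTruth


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng([int(k) % (2**31) for k in keys])


def _random_orf(length_bp: int, rng: np.random.Generator) -> str:
    codons = rng.choice(_SENSE_CODONS, size=length_bp // 3)
    return "".join(codons)


def _noisy_copy(seq: str, rng: np.random.Generator, rate: float = 0.002) -> str:
    """Within-clade sequence noise: random sense-preserving substitutions."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        ci, off = divmod(int(pos), 3)
        codon = "".join(out[3 * ci : 3 * ci + 3])
        options = [
            b for b in BASES
            if b != codon[off]
            and translate_codon(codon[:off] + b + codon[off + 1 :]) != "*"
        ]
        if options:
            out[pos] = options[int(rng.integers(len(options)))]
    return "".join(out)


def simulate_panel(cfg: SimulationConfig) -> SyntheticPanel:
    """Generate the genome panel: sequences, presence/absence and ANI table."""
    clades = cfg.clade_names
    genomes: list[str] = []
    partition: dict[str, str] = {}
    for clade in clades:
        for j in range(cfg.genomes_per_clade):
            gid = f"G{clade}{j:02d}"
            genomes.append(gid)
            partition[gid] = clade

    hk_names = list(HOUSEKEEPING_GENE_NAMES)
    while len(hk_names) < cfg.n_housekeeping:
        hk_names.append(f"hk{len(hk_names) + 1}")
    hk_names = hk_names[: cfg.n_housekeeping]
    # ROARY convention: annotated single-copy clusters carry the gene name
    hk_genes = list(hk_names)
    core_genes = [f"core_{i:04d}" for i in range(cfg.n_core_genes)]
    marker_genes = {
        clade: [f"marker_{clade}_{i:03d}" for i in range(cfg.markers_per_clade)]
        for clade in clades
    }

    gene_ids = hk_genes + core_genes + [g for c in clades for g in marker_genes[c]]
    base_rng = _rng(cfg.seed, 0)
    base_seq = {g: _random_orf(cfg.gene_length_bp, base_rng) for g in gene_ids}

    sequences: dict[str, dict[str, str]] = {g: {} for g in gene_ids}
    presence = pd.DataFrame(0, index=genomes, columns=gene_ids, dtype=np.int8)
    for gi, genome in enumerate(genomes):
        g_rng = _rng(cfg.seed, 1, gi)
        clade = partition[genome]
        carried = hk_genes + core_genes + marker_genes[clade]
        for gene in carried:
            if gene.startswith("core_") and g_rng.random() < 0.02:
                continue  # occasional core dropout, kept above the 95% floor below
            presence.at[genome, gene] = 1
            sequences[gene][genome] = _noisy_copy(base_seq[gene], g_rng)
    # enforce panel-wide core presence >= 95%
    for gene in core_genes:
        frac = presence[gene].mean()
        if frac < 0.95:
            for genome in genomes:
                if presence.at[genome, gene] == 0:
                    presence.at[genome, gene] = 1
                    sequences[gene][genome] = base_seq[gene]

    # private accessory genes give within-clade gene-content diversity
    acc_columns: dict[str, np.ndarray] = {}
    for gi, genome in enumerate(genomes):
        for a in range(cfg.accessory_per_genome):
            col = np.zeros(len(genomes), dtype=np.int8)
            col[gi] = 1
            acc_columns[f"acc_{genome}_{a}"] = col
    if acc_columns:
        presence = pd.concat(
            [presence, pd.DataFrame(acc_columns, index=genomes, dtype=np.int8)], axis=1
        )

    gene_names = {name: name for name in hk_names}
    pam = PresenceAbsenceMatrix(presence, gene_names=gene_names, source_dialect="rtab")

    # synthetic ANI table: tight within clades, separated between clades
    ani_rng = _rng(cfg.seed, 2)
    rows = []
    for i, gi_ in enumerate(genomes):
        for j, gj in enumerate(genomes):
            if i >= j:
                continue
            if partition[gi_] == partition[gj]:
                d = ani_rng.uniform(0.01, 0.03)
            else:
                d = ani_rng.uniform(0.08, 0.12)
            rows.append((gi_, gj, 1.0 - d, 700_000))
            rows.append((gj, gi_, 1.0 - d, 700_000))
    ani_pairs = pd.DataFrame(rows, columns=["id_i", "id_j", "identity", "aln_length"])

    gene_rates: dict[str, float] = {}
    gene_omegas: dict[str, float] = {}
    for g in hk_genes:
        gene_rates[g] = cfg.hk_rate
        gene_omegas[g] = cfg.target_omega_hk
    for g in core_genes:
        gene_rates[g] = cfg.hk_rate * cfg.core_rate_multiplier
        gene_omegas[g] = cfg.target_omega_core
    for clade, mult in zip(clades, cfg.marker_multipliers):
        for g in marker_genes[clade]:
            gene_rates[g] = cfg.hk_rate * mult
            gene_omegas[g] = cfg.target_omega_marker

    truth = SyntheticTruth(
        partition=partition,
        markers=marker_genes,
        housekeeping=hk_genes,
        core=core_genes,
        gene_rates=gene_rates,
        gene_omegas=gene_omegas,
    )
    return SyntheticPanel(pam, sequences, ani_pairs, CladePartition(partition), truth)


def mutate_codon_sequence(
    seq: str,
    rate: float,
    target_omega: float,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> tuple[str, list[tuple[int, str, str, str]]]:
    """Inject substitutions at a per-bp ``rate`` with a synonymous /
    non-synonymous mix tuned to ``target_omega``.

    The number of hits is drawn by per-site Bernoulli sampling at ``rate``.
    Each hit then draws its class — non-synonymous with probability
    omega*N_sites / (omega*N_sites + S_sites), so the expected count ratio
    matches the target after NG86 site normalization — and is placed
    uniformly on a site of an untouched codon that offers a substitution of
    that class.  At most one substitution lands per codon, so every variant's
    class is exact in its codon context (omega = 0 yields dn = 0 exactly) and
    total counts follow the configured rate.  Stop-creating changes are never
    drawn; a class with no remaining feasible site is resampled up to
    ``max_retries`` before the hit is dropped.  Returns (mutated sequence,
    variant list) with 1-based positions and a "syn"/"nonsyn" tag.
    """
    if rate < 0 or rate > 0.5:
        raise ValueError("rate must lie in [0, 0.5]")
    fractions = classify_sites(seq)
    s_sites = float(fractions.sum())
    n_sites = len(seq) - s_sites
    if target_omega == 0:
        p_nonsyn = 0.0
    else:
        p_nonsyn = target_omega * n_sites / (target_omega * n_sites + s_sites)

    # per-site substitution options by class, stop-creating changes excluded
    syn_opts: dict[int, list[str]] = {}
    nonsyn_opts: dict[int, list[str]] = {}
    for pos in range(len(seq)):
        ci, off = divmod(pos, 3)
        codon = seq[3 * ci : 3 * ci + 3]
        aa = translate_codon(codon)
        s_list, n_list = [], []
        for b in BASES:
            if b == codon[off]:
                continue
            mut_aa = translate_codon(codon[:off] + b + codon[off + 1 :])
            if mut_aa == "*":
                continue
            (s_list if mut_aa == aa else n_list).append(b)
        if s_list:
            syn_opts[pos] = s_list
        if n_list:
            nonsyn_opts[pos] = n_list

    n_hits = int((rng.random(len(seq)) < rate).sum())
    out = list(seq)
    variants: list[tuple[int, str, str, str]] = []
    used_codons: set[int] = set()
    for _ in range(n_hits):
        placed = False
        for _ in range(max_retries):
            want_nonsyn = rng.random() < p_nonsyn
            pool = nonsyn_opts if want_nonsyn else syn_opts
            avail = [p for p in pool if p // 3 not in used_codons]
            if not avail:
                continue
            pos = avail[int(rng.integers(len(avail)))]
            options = pool[pos]
            alt = options[int(rng.integers(len(options)))]
            out[pos] = alt
            used_codons.add(pos // 3)
            variants.append(
                (pos + 1, seq[pos], alt, "nonsyn" if want_nonsyn else "syn")
            )
            placed = True
            break
        if not placed:
            continue
    variants.sort()
    return "".join(out), variants


def simulate_sample(
    cfg: SimulationConfig,
    catalog: MarkerCatalog,
    truth: SyntheticTruth,
    sample_index: int,
) -> SyntheticSample:
    """Generate one sample: clade presence, marker/gene coverage and SNVs."""
    sample_id = f"S{sample_index:04d}"
    rng = _rng(cfg.seed, 10, sample_index)
    clades = cfg.clade_names
    present = {c: bool(rng.random() < cfg.clade_presence_prob) for c in clades}
    any_present = any(present.values())

    depths: dict[str, float] = {}
    abundance: dict[str, float] = {}

    def draw_depth(r: np.random.Generator) -> float:
        return float(r.gamma(shape=20.0, scale=cfg.coverage_mean / 20.0))

    for clade in clades:
        if present[clade]:
            for g in truth.markers[clade]:
                depths[g] = draw_depth(rng)
            abundance[clade] = (
                cfg.coverage_mean * cfg.genome_size_bp / cfg.metagenome_size_bp
            )
        else:
            abundance[clade] = 0.0
    if any_present:
        for g in truth.housekeeping + truth.core:
            depths[g] = draw_depth(rng)

    variants: dict[str, list[VariantRecord]] = {}
    sample_truth_variants: dict[str, dict[str, int]] = {}
    observed_genes = sorted(depths)
    for gene in observed_genes:
        if gene not in catalog.sequences:
            continue
        g_rng = _rng(cfg.seed, 10, sample_index, zlib.crc32(gene.encode()))
        ref = catalog.sequences[gene]
        _, muts = mutate_codon_sequence(
            ref, truth.gene_rates[gene], truth.gene_omegas[gene], g_rng
        )
        recs = []
        for pos, ref_b, alt_b, kind in muts:
            recs.append(
                VariantRecord(
                    gene_id=gene,
                    position=pos,
                    ref=ref_b,
                    alt=alt_b,
                    depth=int(g_rng.integers(10, 61)),
                    qual=float(g_rng.uniform(201.0, 999.0)),
                )
            )
        if cfg.filter_fail_fraction > 0:
            used = {r.position for r in recs}
            free = [p for p in range(1, len(ref) + 1) if p not in used]
            n_fail = int(round(cfg.filter_fail_fraction * max(len(recs), 1)))
            for pos in g_rng.choice(free, size=min(n_fail, len(free)), replace=False):
                pos = int(pos)
                ref_b = ref[pos - 1]
                alt_b = next(b for b in BASES if b != ref_b)
                # boundary-pinning failures: depth 9 (too shallow) or qual 200 (not > 200)
                if g_rng.random() < 0.5:
                    recs.append(VariantRecord(gene, pos, ref_b, alt_b, 9, 500.0))
                else:
                    recs.append(VariantRecord(gene, pos, ref_b, alt_b, 30, 200.0))
        variants[gene] = sorted(recs, key=lambda r: r.position)
        sample_truth_variants[gene] = {
            "n": len(muts),
            "syn": sum(1 for m in muts if m[3] == "syn"),
            "nonsyn": sum(1 for m in muts if m[3] == "nonsyn"),
        }

    coverage = MarkerCoverage(
        sample_id=sample_id,
        depths=depths,
        metagenome_size_bp=cfg.metagenome_size_bp,
        species_relative_abundance=float(sum(abundance.values())),
    )
    truth.samples[sample_id] = {
        "clade_presence": present,
        "clade_abundance": abundance,
        "variants": sample_truth_variants,
    }
    return SyntheticSample(sample_id, coverage, variants)


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Full synthetic dataset: panel, catalog, samples, manifest and metadata."""
    panel = simulate_panel(cfg)
    catalog = build_catalog(
        panel.pam,
        panel.partition,
        sequences=panel.sequences,
        n_core=cfg.n_core_genes,
        housekeeping_names=tuple(panel.truth.housekeeping),
        seed=cfg.seed,
    )
    samples = [
        simulate_sample(cfg, catalog, panel.truth, i) for i in range(cfg.n_samples)
    ]
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "metagenome_size_bp": [s.coverage.metagenome_size_bp for s in samples],
            "species_relative_abundance": [
                s.coverage.species_relative_abundance for s in samples
            ],
        }
    )
    pops = cfg.populations
    meta_rows = []
    for i, s in enumerate(samples):
        pop, lifestyle = pops[i % len(pops)]
        meta_rows.append((s.sample_id, pop, lifestyle, "adult"))
        panel.truth.samples[s.sample_id]["population"] = pop
        panel.truth.samples[s.sample_id]["lifestyle"] = lifestyle
    metadata = CohortMetadata.from_frame(
        pd.DataFrame(meta_rows, columns=["sample_id", "population", "lifestyle", "age_group"])
    )
    return SyntheticCohort(cfg, panel, catalog, samples, manifest, metadata, panel.truth)
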