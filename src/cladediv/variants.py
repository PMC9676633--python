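"""Per-gene variant statistics from metagenome-derived haploid SNV calls.

Implements the variant-level half of the divergence analysis:

* depth/quality filtering of VCF records with a one-SNP-per-position rule,
* SNP-per-base rates (filtered SNP count divided by gene length),
* consensus reconstruction by substituting alternate alleles into the
  reference gene sequence,
* pairwise dN/dS by the Nei-Gojobori (1986) counting method with
  Jukes-Cantor correction, validity-gated by a 0.01 < dS < 2 window,
* Tajima's D per gene (all sites or synonymous sites only).

Coordinates are 1-based on the gene's representative sequence; VCF CHROM is
the gene identifier and calls are haploid single-nucleotide substitutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "VariantRecord",
    "GeneVariantStats",
    "NG86Result",
    "TajimaResult",
    "filter_variants",
    "snp_per_base",
    "build_consensus",
    "classify_sites",
    "ng86_dnds",
    "tajimas_d",
    "gene_variant_stats",
]

BASES = ("A", "C", "G", "T")
_STOPS = frozenset(standard_dna_table.stop_codons)
_FORWARD = dict(standard_dna_table.forward_table)


def translate_codon(codon: str) -> str:
    """Amino acid of a codon; stop codons translate to '*'."""
    if codon in _STOPS:
        return "*"
    try:
        return _FORWARD[codon]
    except KeyError as exc:
        raise ValueError(f"invalid codon {codon!r}") from exc


@dataclass(frozen=True)
class VariantRecord:
    """A haploid single-nucleotide variant on a gene's representative sequence."""

    gene_id: str
    position: int  # 1-based
    ref: str
    alt: str
    depth: int
    qual: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.gene_id}:{self.position}: position must be >= 1")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"{self.gene_id}:{self.position}: only single-base SNVs supported "
                f"(ref={self.ref!r}, alt={self.alt!r})"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.gene_id}:{self.position}: ref equals alt")
        if self.depth < 0 or self.qual < 0:
            raise ValueError(f"{self.gene_id}:{self.position}: negative depth or qual")


@dataclass
class NG86Result:
    dn: float
    ds: float
    omega: float  # NaN when invalid
    omega_valid: bool
    reason: str = ""
    n_sites: float = 0.0
    s_sites: float = 0.0


@dataclass
class GeneVariantStats:
    sample_id: str
    gene_id: str
    snp_count: int
    gene_length_bp: int
    snp_per_base: float
    dn: float
    ds: float
    omega: float
    omega_valid: bool


@dataclass
class TajimaResult:
    n: int
    S: float
    pi: float
    D: float  # NaN when undefined
    defined: bool
    mask: str = "all"
    total_sites: float = float("nan")


def filter_variants(
    records: Iterable[VariantRecord],
    min_depth: int = 10,
    min_qual: float = 200.0,
) -> list[VariantRecord]:
    """Depth/quality filter plus the one-point-mutation-per-position rule.

    Keeps records with depth >= min_depth and qual strictly > min_qual, then
    retains a single record per (gene, position): highest qual, ties broken by
    highest depth then lexicographically smallest alternate allele.
    Idempotent by construction.
    """
    surviving: dict[tuple[str, int], VariantRecord] = {}
    for rec in records:
        if rec.depth < min_depth or rec.qual <= min_qual:
            continue
        key = (rec.gene_id, rec.position)
        best = surviving.get(key)
        if best is None or (-rec.qual, -rec.depth, rec.alt) < (-best.qual, -best.depth, best.alt):
            surviving[key] = rec
    return [surviving[k] for k in sorted(surviving)]


def snp_per_base(filtered: Sequence[VariantRecord], gene_length_bp: int) -> float:
    """Distinct variant positions divided by gene length (bp)."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be positive")
    positions = set()
    for rec in filtered:
        if rec.position > gene_length_bp:
            raise ValueError(
                f"{rec.gene_id}: variant position {rec.position} beyond gene "
                f"length {gene_length_bp}"
            )
        positions.add(rec.position)
    return len(positions) / gene_length_bp


def build_consensus(ref_seq: str, filtered: Sequence[VariantRecord]) -> str:
    """Substitute each variant's alternate allele into the reference sequence."""
    seq = list(ref_seq)
    for rec in filtered:
        if rec.position > len(ref_seq):
            raise ValueError(
                f"{rec.gene_id}: position {rec.position} beyond reference length {len(ref_seq)}"
            )
        have = ref_seq[rec.position - 1]
        if have != rec.ref:
            raise ValueError(
                f"{rec.gene_id}:{rec.position}: reference mismatch "
                f"(record ref {rec.ref!r}, sequence has {have!r})"
            )
        seq[rec.position - 1] = rec.alt
    return "".join(seq)


def _check_orf(seq: str, name: str = "sequence") -> None:
    if len(seq) % 3 != 0 or len(seq) < 3:
        raise ValueError(f"{name} length {len(seq)} is not a positive multiple of 3")
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in _STOPS:
            raise ValueError(f"{name} has internal stop codon at nt {i + 1}")


def classify_sites(ref_codons: str) -> np.ndarray:
    """Per-nucleotide synonymous site fractions under the standard code.

    For each position, the fraction of the 3 possible substitutions that
    preserve the amino acid (changes creating a stop count as non-synonymous).
    Gene totals: S_sites = sum of fractions, N_sites = length - S_sites.
    """
    _check_orf(ref_codons, "reference")
    fractions = np.empty(len(ref_codons))
    for ci in range(len(ref_codons) // 3):
        codon = ref_codons[3 * ci : 3 * ci + 3]
        aa = translate_codon(codon)
        for off in range(3):
            syn = 0
            for b in BASES:
                if b == codon[off]:
                    continue
                mutant = codon[:off] + b + codon[off + 1 :]
                if translate_codon(mutant) == aa:
                    syn += 1
            fractions[3 * ci + off] = syn / 3.0
    return fractions


def _codon_site_fractions(codon: str) -> float:
    """Total synonymous sites of one codon (sum over its 3 positions)."""
    aa = translate_codon(codon)
    syn = 0
    for off in range(3):
        for b in BASES:
            if b == codon[off]:
                continue
            mutant = codon[:off] + b + codon[off + 1 :]
            if translate_codon(mutant) == aa:
                syn += 1
    return syn / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous difference counts between two codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded unless every pathway does.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            if nxt in _STOPS and nxt != c2:
                blocked = True
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if translate_codon(a) == translate_codon(b):
                syn += 1
            else:
                nonsyn += 1
    k = len(usable)
    return syn / k, nonsyn / k


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_dnds(
    ref_codons: str,
    alt_codons: str,
    ds_min: float = 0.01,
    ds_max: float = 2.0,
) -> NG86Result:
    """Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

    Synonymous/non-synonymous site counts are averaged over the two sequences;
    observed differences are resolved by averaging over all minimal
    substitution pathways.  omega = dN/dS is flagged valid only when
    ds_min < dS < ds_max and both corrected distances are finite — the window
    excludes near-identical and saturated pairs whose estimates are unreliable.
    """
    if len(ref_codons) != len(alt_codons):
        raise ValueError("sequences must have equal length")
    _check_orf(ref_codons, "reference")
    if len(alt_codons) % 3 != 0:
        raise ValueError("alternate sequence length is not a multiple of 3")
    n_codons = len(ref_codons) // 3
    s1 = s2 = 0.0
    sd = nd = 0.0
    for ci in range(n_codons):
        a = ref_codons[3 * ci : 3 * ci + 3]
        b = alt_codons[3 * ci : 3 * ci + 3]
        s1 += _codon_site_fractions(a)
        s2 += _codon_site_fractions(b)
        syn, nonsyn = _pathway_counts(a, b)
        sd += syn
        nd += nonsyn
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    if math.isnan(ds) or math.isnan(dn):
        return NG86Result(dn, ds, float("nan"), False, "jukes_cantor_saturated",
                          n_sites, s_sites)
    if not (ds_min < ds < ds_max):
        reason = "ds_below_min" if ds <= ds_min else "ds_above_max"
        return NG86Result(dn, ds, float("nan"), False, reason, n_sites, s_sites)
    return NG86Result(dn, ds, dn / ds, True, "", n_sites, s_sites)


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _synonymous_column(ref_seq: str, pos: int, alleles: set[str]) -> bool:
    """True iff every observed allele pair at ``pos`` (0-based) is a
    synonymous exchange in its reference codon context."""
    ci, off = divmod(pos, 3)
    codon = ref_seq[3 * ci : 3 * ci + 3]
    aas = set()
    for b in alleles:
        mutant = codon[:off] + b + codon[off + 1 :]
        aas.add(translate_codon(mutant))
    return len(aas) == 1 and "*" not in aas


def tajimas_d(
    sequences: Sequence[str],
    synonymous: bool = False,
    ref_seq: str | None = None,
) -> TajimaResult:
    """Tajima (1989) D over an alignment of n >= 3 equal-length sequences.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with pi the mean pairwise
    difference count and S the number of segregating sites.  With
    ``synonymous=True``, segregating sites are counted only where every
    observed allele pair is a synonymous exchange in the reference codon
    context, and pi is restricted to those sites; the fractional synonymous
    site total of the reference is reported as ``total_sites``.
    """
    n = len(sequences)
    if n < 3:
        raise ValueError("Tajima's D requires at least 3 sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be aligned to equal lengths")
    alphabet = set("".join(sequences))
    if not alphabet <= set(BASES):
        raise ValueError(f"unexpected characters in alignment: {sorted(alphabet - set(BASES))}")
    mask_tag = "synonymous" if synonymous else "all"
    total_sites = float(length)
    if synonymous:
        if ref_seq is None:
            raise ValueError("synonymous mask requires a reference sequence")
        total_sites = float(classify_sites(ref_seq).sum())

    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(n, length)
    S = 0
    pairwise_diffs = 0.0
    n_pairs = n * (n - 1) / 2.0
    variable = np.flatnonzero((arr != arr[0]).any(axis=0))
    for pos in variable:
        col = arr[:, pos]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) < 2:
            continue
        if synonymous:
            obs = {a.decode() for a in alleles}
            if not _synonymous_column(ref_seq, pos, obs):
                continue
        S += 1
        same = (counts * (counts - 1) / 2.0).sum()
        pairwise_diffs += n_pairs - same
    if S == 0:
        return TajimaResult(n, 0, 0.0, float("nan"), False, mask_tag, total_sites)
    pi = pairwise_diffs / n_pairs
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # n=3 with a single segregating site has zero variance
        return TajimaResult(n, S, pi, float("nan"), False, mask_tag, total_sites)
    D = (pi - S / a1) / math.sqrt(var)
    return TajimaResult(n, S, pi, D, True, mask_tag, total_sites)


def gene_variant_stats(
    sample_id: str,
    gene_id: str,
    records: Iterable[VariantRecord],
    ref_seq: str,
    min_depth: int = 10,
    min_qual: float = 200.0,
    ds_min: float = 0.01,
    ds_max: float = 2.0,
    compute_dnds: bool = True,
) -> GeneVariantStats:
    """Assemble per-(sample, gene) statistics: SNP-per-base and pairwise dN/dS
    between the catalog reference and the sample consensus."""
    filtered = filter_variants(records, min_depth=min_depth, min_qual=min_qual)
    rate = snp_per_base(filtered, len(ref_seq))
    dn = ds = omega = float("nan")
    valid = False
    if compute_dnds:
        consensus = build_consensus(ref_seq, filtered)
        res = ng86_dnds(ref_seq, consensus, ds_min=ds_min, ds_max=ds_max)
        dn, ds, omega, valid = res.dn, res.ds, res.omega, res.omega_valid
    return GeneVariantStats(
        sample_id=sample_id,
        gene_id=gene_id,
        snp_count=len(filtered),
        gene_length_bp=len(ref_seq),
        snp_per_base=rate,
        dn=dn,
        ds=ds,
        omega=omega,
        omega_valid=valid,
    )
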