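# Methods

This note documents the models, conventions and design choices behind
`cladediv`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, with which defaults,
and what the synthetic validation does and does not demonstrate.

## Clade definition

Genome-content distance is Jaccard dissimilarity on gene presence/absence
sets, d(i,j) = 1 − |G_i ∩ G_j| / |G_i ∪ G_j|; a genome with an empty gene
set is rejected (the distance is undefined). ANI-based distance is
1 − identity from a long-format table of directed pairwise comparisons;
pairs whose alignment length does not *exceed* 500 kb (strictly) are treated
as missing, directed values are averaged, and a pair present in only one
direction is used as-is with a warning.

Clustering is agglomerative Ward linkage applied to the dissimilarities
directly (the Ward.D2 convention — appropriate because the inputs are
non-Euclidean dissimilarities; a `variant="D"` option reproduces the
classic Ward.D recursion by feeding square roots through the same update).
The tree is cut to exactly k clades. k is a deliberate user parameter: the
number of clades in a species complex is a scientific judgement, so rather
than hard-coding a cut rule the package reports mean silhouette widths over
k ∈ [2, 12] (`silhouette_profile`) to inform the choice. Clade labels are
deterministic: A, B, C, … by decreasing size, ties broken by the
lexicographically smallest member, so repeated runs are comparable.

When both gene-content and ANI partitions are available they are combined
by the partition meet (`consensus_partition`): genomes are co-claded only
if co-claded in both. This is the conservative resolution of disagreement
between the two clusterings; singleton clades produced by the meet are
flagged so the user can drop or re-assign them. Matrices with missing
cells are refused by the clustering step — imputation is the user's
decision, not the package's.

PERMANOVA validates a partition on either matrix: pseudo-F from among- and
within-group sums of squared distances, p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_permutations) under free label permutation (no strata), 999
permutations by default. All pairwise two-group tests are reported with
Benjamini–Hochberg q-values; the conventional significance threshold for
clade separation is FDR < 0.001. The permutation engine is in-package so
one seed controls the whole run; tests cross-check the statistic against
scikit-bio's implementation.

## Marker catalog

A gene is a marker of clade c iff its presence fraction within c is ≥ 0.95
(inclusive) *and* it is absent from every genome of every other clade.
Outgroup genomes are ignored. The absence condition forces marker sets to
be pairwise disjoint, which is asserted on every catalog. "Present" in the
ROARY CSV dialect means a non-empty cell; paralog-split entries count once.
Core genes are present in ≥ 95% of the whole panel; 500 of them (default)
are sampled uniformly without replacement under a fixed seed as the neutral
control, excluding the housekeeping panel. The housekeeping baseline is the
ten-gene essential panel (recA, rplS, rplI, purN, mreB, maf, fmt, gyrB,
rpoB, proC), resolved case-insensitively against the pangenome gene-name
annotation (falling back to the cluster id, since ROARY names single-copy
annotated clusters by gene name) and required to be present in 100% of
panel genomes — a violation is an error naming the offenders, not a silent
drop. Each catalog gene carries one representative nucleotide sequence: the
copy from the lexicographically smallest genome carrying it, a deterministic
choice that fixes the coordinate system for all variant work.

## Metagenome profiling

A marker is *hit* in a sample when its mean depth is ≥ 0.5X (inclusive); a
clade is *present* when ≥ 50% (inclusive) of its markers are hit. Markers
absent from the coverage table count as depth 0. Clade relative abundance
is mean depth over **all** clade markers (zeros included) × genome size /
metagenome size; a single configurable species-level genome size (default
3 Mb) is used for all clades. Averaging over hit markers only is available
(`mean_over_hit_only`) but off by default. Samples below the species-level
gate (default 1% species relative abundance, from the sample manifest) are
excluded from variant analysis but retained in prevalence summaries.
Cohort summaries report per-group prevalence and clade co-presence by age
group, population and lifestyle, with Fisher's exact tests on presence and
Mann–Whitney tests on per-sample clade counts, Bonferroni corrected. The
age bins are the printed ones (infant < 1, child 1–16, adult 18–69, elderly
70–97, centenarian > 99); ages 17 and 98–99 fall between bins and are
rejected unless an explicit group is supplied.

## Variant statistics

Input is haploid single-nucleotide VCF with CHROM = gene id and 1-based
positions on the gene's representative sequence; indels are out of scope
and rejected. Filtering keeps records with depth ≥ 10 (inclusive) and QUAL
strictly > 200, then retains one record per position (highest QUAL, ties by
depth, then lexicographically smallest alternate allele); the filter is
idempotent. SNP-per-base is the count of distinct surviving positions over
gene length. The sample consensus substitutes each surviving alternate into
the representative sequence, so consensus and reference are colinear by
construction and no protein re-alignment step is needed.

dN/dS is the Nei–Gojobori (1986) counting estimator: per-codon synonymous
site fractions (each position contributes the fraction of its three
substitutions that preserve the amino acid; stop-creating changes count as
non-synonymous) averaged over the two sequences; observed differences
resolved by averaging over all minimal substitution pathways, excluding
pathways through stop intermediates unless all are blocked; Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)p) applied to both proportions. omega =
dN/dS is reported valid only when 0.01 < dS < 2 and both corrections are
finite — near-identical and saturated pairs give unreliable ratios and are
flagged with a reason instead. A maximum-likelihood codon-model estimator
would be an alternative; the counting estimator is deterministic,
dependency-free and adequate for the rate-ratio use made of it here, and
the dS window applies identically either way.

Tajima's D follows the 1989 definitions: D = (π − S/a₁) / √(e₁S + e₂S(S−1))
with the usual a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constants, π the mean
pairwise difference count and S the number of segregating sites; S = 0 (and
the n = 3, S = 1 zero-variance corner) is undefined and flagged rather than
returned as a number. The haplotype set for a (clade, gene) pair is the
consensus sequences across all gated samples in which the clade is present,
one window per gene (n ≥ 3 required). This across-sample reading of
"individuals" in a metagenomic setting is one defensible choice and is
documented as such, not asserted as unique. In synonymous mode a
segregating site counts only if every observed allele pair is a synonymous
exchange in its reference codon context, π is restricted to those sites,
and the fractional synonymous site total of the reference is reported
alongside.

## Divergence indices

Per sample: M_H = median SNP-per-base over the housekeeping genes observed
in the sample, μ_H = mean of their valid omegas (the median/mean asymmetry
between M and μ aggregation is intentional and kept throughout); M_E /
μ_E analogously over a clade's observed markers; DRIc = ln(M_E/M_H),
DRIg = ln(M_G/M_H), NDRIc = ln(μ_E/μ_H), NDRIg = ln(μ_G/μ_H). Genes with
invalid omega contribute to no μ statistic (never as zeros). M_E uses only
the markers observed in the sample (absent markers are not imputed as
zero). A clade with no observed markers gets missing indices, never zeros.

Zero rules: denominator zero → substitute the global floor, the smallest
nonzero M_H (resp. μ_H) over all gated samples of the run, computed once
per cohort and recorded in the run manifest; both zero → index 0;
numerator zero → a non-diverging sentinel that is excluded by the
strict-positivity filter and participates in medians as the most-negative
rank (implemented as −inf with rank-based quantiles, so no arithmetic is
ever done on it). Global and per-population aggregates are medians with
25th/75th percentiles over samples with non-missing values; missing-clade
samples contribute nothing. Diverging markers are genes with global
DRIg > 0 *and* NDRIg > 0, strictly.

Baseline validation computes Pearson correlations of M_H and μ_H against
metagenome length and species abundance, and of gene prevalence against
global DRIg/NDRIg; the design expectation is no significant correlation,
so any p ≤ 0.05 raises a coverage-bias warning, and zero-variance inputs
are reported as undefined rather than silently skipped.

## Synthetic cohort generator

The generator emulates the emulated study design at desk scale with full
ground truth. Defaults: 5 clades × 10 genomes, 12 markers per clade
(present in every clade genome, absent elsewhere), 60 core genes (≥ 95%
panel presence with ~2% per-genome dropout), 10 universal housekeeping
genes, 8 private accessory genes per genome (so gene-content distances
separate clades without being degenerate within them), 900 bp random
stop-free ORFs per gene with small sense-preserving within-clade noise, a
synthetic ANI table (within-clade distance U(0.01, 0.03), between
U(0.08, 0.12)), 50 samples assigned round-robin to five populations across
three lifestyles, per-clade presence probability 0.8, mean coverage 5X
(gamma-distributed per gene, CV ≈ 0.22), metagenome size 2 Gb and genome
size 3 Mb (per-clade planted abundance 0.75%, so typical samples clear the
1% species gate with 2+ clades present). The housekeeping per-bp SNP rate
is 0.01 — large enough that median-of-counts discreteness does not dominate
the log-ratios at 900 bp — with clade markers at e × that rate (planted
DRI exactly 1) and core genes at 1×; target omegas are 0.2 for
housekeeping/core (purifying) and 0.4 for markers (planted NDRI = ln 2).

Mutation injection: the number of substitutions per gene copy is drawn by
per-site Bernoulli sampling at the gene's rate; each hit then draws its
class — non-synonymous with probability ωN/(ωN + S) where S and N are the
gene's NG86 site totals, so the expected count ratio matches the target
omega after site normalization — and lands uniformly on a site of a
still-untouched codon offering a substitution of that class. At most one
substitution per codon means every injected variant's class is exact in its
codon context: target ω = 0 yields dN = 0 exactly, and the total count
follows the configured rate. Stop-creating changes are never drawn; an
infeasible class draw is retried and ultimately dropped. The omega tuning
uses the same NG86 site convention as the estimator — a deliberate
co-design that makes recovery tests internally consistent; circularity is
guarded against by the independent brute-force pathway-enumeration oracle
in the test suite.

VCF records for injected variants carry depths uniform in [10, 60] and QUAL
uniform in (201, 999]; optionally a fraction of planted filter-failing
records is added exactly at the boundary values (depth 9, QUAL 200.0) to
pin the inclusive/strict filter conventions. Randomness is hierarchical —
one seed, with independent streams derived per panel, per sample and per
(sample, gene) via stable integer keys — so regeneration is bit-identical
and adding samples never perturbs earlier ones.

What the generator does *not* emulate: read-level sequencing error,
assembly/binning artifacts, strain mixtures within a clade in one sample,
linkage between sites (all injected variants are independent), compositional
coverage bias, and contamination. Passing the recovery tests therefore
shows the estimators and index algebra are correct under the stated
sampling model, not that the pipeline is robust to every real-data
pathology; the variant filters and the baseline-correlation screen are the
designed defenses for those.

A consequence of injecting independent per-sample variants is an excess of
rare alleles across the consensus haplotypes, so synthetic Tajima's D values
are strongly negative (≈ −2 to −3 at the defaults) for markers and core
genes alike — the generator reproduces the direction of a purifying /
post-sweep signature, not any particular published magnitude.

## Numerical and procedural choices

- Problem sizes in the test suite and acceptance script (10–50 samples,
  60 core genes, 900 bp genes, 99–999 permutations, 50 Monte-Carlo
  replicates) are chosen to keep the whole validation desk-scale while
  leaving Monte-Carlo noise well inside the asserted tolerances.
- Distances are validated to be symmetric within 1e-12 with zero diagonal
  and values in [0, 1]; Ward clustering refuses missing cells.
- The one-record-per-position filter breaks exact ties deterministically
  (QUAL, then depth, then lexicographic alternate allele).
- PERMANOVA returns the +1-corrected permutation p-value, so the minimum
  attainable p with 999 permutations is 1/1000.
- All medians/quantiles involving the non-diverging sentinel use rank-based
  methods; quartiles of purely finite values use linear interpolation.
- Degenerate inputs error loudly and early: empty gene sets, empty clades,
  unresolved or non-universal housekeeping genes, reference-allele
  mismatches (a sign of coordinate confusion), indel records, alignments
  with fewer than three sequences.

## Known limitations

- The pairwise dN/dS counting estimator is downward-biased relative to ML
  estimators at high divergence and ignores transition/transversion bias;
  within the 0.01 < dS < 2 window used here the bias is small relative to
  the index tolerances.
- Tajima's D on across-sample consensus sequences treats each sample's
  consensus as one haplotype; within-sample strain diversity is invisible.
- The abundance estimate assumes markers are single-copy and the species
  genome size is clade-invariant.
- The consensus-based partition meet can oversplit when the two distance
  matrices disagree noisily; silhouette guidance and PERMANOVA output are
  provided to diagnose this rather than an automatic repair.
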