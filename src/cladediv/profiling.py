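"""Metagenome-level clade detection, abundance estimation and cohort summaries.

A clade marker is scored present in a sample when its mean read depth is
>= 0.5X (inclusive); a clade is called present when at least 50% of its
markers are hit.  Clade relative abundance is the mean depth over all clade
markers (absent markers as zero) times the species genome size divided by the
metagenome size.  Cohort summaries report prevalence and clade co-presence by
age group, population and lifestyle with Fisher's exact tests (Bonferroni
corrected) and rank tests on per-sample clade counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from .markers import MarkerCatalog

__all__ = [
    "MarkerCoverage",
    "CladeCall",
    "CohortMetadata",
    "score_marker_presence",
    "call_clade",
    "estimate_abundance",
    "profile_sample",
    "summarize_cohort",
]

LIFESTYLES = ("industrial-urban", "rural", "hunter-gatherer")

# age -> printed age-group bins; 17 and 98-99 fall between bins and are
# rejected unless an explicit override supplies the group
AGE_BINS = (
    ("infant", 0.0, 1.0),       # < 1
    ("child", 1.0, 17.0),       # 1-16
    ("adult", 18.0, 70.0),      # 18-69
    ("elderly", 70.0, 98.0),    # 70-97
    ("centenarian", 99.0, float("inf")),  # > 99
)
AGE_GROUPS = tuple(b[0] for b in AGE_BINS)


def age_to_group(age: float) -> str:
    if age < 1:
        return "infant"
    if 1 <= age < 17:
        return "child"
    if 18 <= age < 70:
        return "adult"
    if 70 <= age < 98:
        return "elderly"
    if age > 99:
        return "centenarian"
    raise ValueError(f"age {age} falls outside the defined age-group bins")


@dataclass
class MarkerCoverage:
    """Per-sample mean depth (X) over catalog genes."""

    sample_id: str
    depths: dict[str, float]
    metagenome_size_bp: int
    species_relative_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.metagenome_size_bp <= 0:
            raise ValueError("metagenome_size_bp must be positive")
        bad = [g for g, d in self.depths.items() if d < 0]
        if bad:
            raise ValueError(f"negative depths for genes: {sorted(bad)[:5]}")

    def depth(self, gene_id: str) -> float:
        # genes missing from the table are uncovered
        return self.depths.get(gene_id, 0.0)


@dataclass
class CladeCall:
    sample_id: str
    clade: str
    fraction_markers_hit: float
    present: bool
    relative_abundance: float


@dataclass
class CohortMetadata:
    """Sample metadata with controlled vocabularies."""

    df: pd.DataFrame  # index sample_id; columns population, lifestyle, age_group

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        bad_ls = set(self.df["lifestyle"]) - set(LIFESTYLES)
        if bad_ls:
            raise ValueError(f"unknown lifestyle labels: {sorted(bad_ls)}")
        bad_ag = set(self.df["age_group"]) - set(AGE_GROUPS)
        if bad_ag:
            raise ValueError(f"unknown age groups: {sorted(bad_ag)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortMetadata":
        df = df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if "age_group" not in df.columns:
            if "age" not in df.columns:
                raise ValueError("metadata needs an age_group or age column")
            df["age_group"] = [age_to_group(a) for a in df["age"]]
        return cls(df[["population", "lifestyle", "age_group"]])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)


def score_marker_presence(depth: float, min_cov: float = 0.5) -> bool:
    """A marker is present iff mean depth >= min_cov (inclusive)."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return depth >= min_cov


def call_clade(
    cov: MarkerCoverage,
    catalog: MarkerCatalog,
    clade: str,
    clade_fraction: float = 0.5,
    min_cov: float = 0.5,
    genome_size_bp: int = 3_000_000,
) -> CladeCall:
    """Call a clade present iff >= clade_fraction of its markers are hit."""
    markers = catalog.markers.get(clade, [])
    if not markers:
        raise ValueError(f"clade {clade} has no markers")
    hits = sum(score_marker_presence(cov.depth(g), min_cov) for g in markers)
    fraction = hits / len(markers)
    return CladeCall(
        sample_id=cov.sample_id,
        clade=clade,
        fraction_markers_hit=fraction,
        present=fraction >= clade_fraction,
        relative_abundance=estimate_abundance(cov, catalog, clade, genome_size_bp),
    )


def estimate_abundance(
    cov: MarkerCoverage,
    catalog: MarkerCatalog,
    clade: str,
    genome_size_bp: int = 3_000_000,
) -> float:
    """Clade relative abundance: mean marker depth x genome size / metagenome size.

    The mean runs over all clade markers, counting markers missing from the
    coverage table as depth zero.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    markers = catalog.markers.get(clade, [])
    if not markers:
        raise ValueError(f"clade {clade} has no markers")
    mean_depth = float(np.mean([cov.depth(g) for g in markers]))
    return mean_depth * genome_size_bp / cov.metagenome_size_bp


def profile_sample(
    cov: MarkerCoverage,
    catalog: MarkerCatalog,
    clade_fraction: float = 0.5,
    min_cov: float = 0.5,
    genome_size_bp: int = 3_000_000,
) -> list[CladeCall]:
    return [
        call_clade(cov, catalog, clade, clade_fraction, min_cov, genome_size_bp)
        for clade in catalog.clades
    ]


def calls_to_frame(calls: Iterable[CladeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.sample_id, c.clade, c.fraction_markers_hit, c.present, c.relative_abundance)
            for c in calls
        ],
        columns=["sample_id", "clade", "fraction_hit", "present", "abundance"],
    )


def _pairwise_group_tests(presence: pd.Series, counts: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Fisher's exact test on any-clade presence and Mann-Whitney on clade
    counts for every pair of groups, Bonferroni corrected."""
    rows = []
    names = sorted(groups.dropna().unique())
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        in_a, in_b = groups == a, groups == b
        table = [
            [int(presence[in_a].sum()), int((~presence[in_a]).sum())],
            [int(presence[in_b].sum()), int((~presence[in_b]).sum())],
        ]
        _, p_fisher = fisher_exact(table)
        ca, cb = counts[in_a], counts[in_b]
        if len(ca) and len(cb) and (len(set(ca)) > 1 or len(set(cb)) > 1 or ca.iloc[0] != cb.iloc[0]):
            _, p_rank = mannwhitneyu(ca, cb, alternative="two-sided")
        else:
            p_rank = 1.0
        rows.append((a, b, p_fisher, p_rank))
    df = pd.DataFrame(rows, columns=["group_1", "group_2", "fisher_p", "rank_p"])
    m = max(len(df), 1)
    df["fisher_p_bonferroni"] = np.minimum(df["fisher_p"] * m, 1.0)
    df["rank_p_bonferroni"] = np.minimum(df["rank_p"] * m, 1.0)
    return df


def summarize_cohort(calls: pd.DataFrame, meta: CohortMetadata) -> dict:
    """Prevalence / co-presence summary of clade calls across a cohort.

    Returns a dict with overall prevalence, per-clade prevalence, the
    distribution of per-sample clade counts, per-group prevalence and
    pairwise group comparisons for each metadata facet.
    """
    unknown = set(calls["sample_id"]) - set(meta.sample_ids)
    if unknown:
        raise ValueError(f"calls reference samples missing from metadata: {sorted(unknown)[:5]}")
    present = calls[calls["present"]]
    counts = (
        present.groupby("sample_id").size().reindex(meta.sample_ids, fill_value=0)
    )
    any_present = counts > 0
    per_clade = {
        clade: float(sub["present"].mean())
        for clade, sub in calls.groupby("clade")
    }
    summary: dict = {
        "n_samples": int(len(meta.sample_ids)),
        "overall_prevalence": float(any_present.mean()),
        "per_clade_prevalence": per_clade,
        "clade_count_distribution": {
            int(k): int(v) for k, v in counts.value_counts().sort_index().items()
        },
        "groups": {},
        "pairwise": {},
    }
    for facet in ("age_group", "population", "lifestyle"):
        groups = meta.df[facet]
        summary["groups"][facet] = {
            str(name): {
                "n": int((groups == name).sum()),
                "prevalence": float(any_present[groups == name].mean()),
                "mean_clade_count": float(counts[groups == name].mean()),
            }
            for name in sorted(groups.unique())
        }
        summary["pairwise"][facet] = _pairwise_group_tests(any_present, counts, groups)
    return summary
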