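"""Clade delineation: Ward clustering of genome distances and PERMANOVA validation.

Genomes are partitioned into clades by hierarchical Ward-linkage clustering of
a dissimilarity matrix (gene-content Jaccard and/or ANI distance); when both
matrices are available the two partitions are combined by a partition meet
(genomes are co-claded only if co-claded in both).  The resulting partition is
validated by permutational multivariate ANOVA (pseudo-F on among/within sums
of squared distances with a label-permutation null).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .pangenome import DistanceMatrix

__all__ = [
    "CladePartition",
    "ward_cluster",
    "consensus_partition",
    "permanova",
    "PermanovaResult",
    "silhouette_profile",
]


def clade_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — deterministic clade label sequence."""
    letters = string.ascii_uppercase
    out: list[str] = []
    k = 1
    while len(out) < n:
        for combo in itertools.product(letters, repeat=k):
            out.append("".join(combo))
            if len(out) == n:
                break
        k += 1
    return out


@dataclass
class CladePartition:
    """Assignment of each panel genome to exactly one clade label."""

    assignment: dict[str, str]
    outgroup_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("partition must contain at least one genome")
        if any(not lab for lab in self.assignment.values()):
            raise ValueError("clade labels must be non-empty strings")
        overlap = set(self.assignment) & set(self.outgroup_ids)
        if overlap:
            raise ValueError(f"genomes both assigned and outgroup: {sorted(overlap)}")

    @property
    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, lab in self.assignment.items():
            out.setdefault(lab, []).append(g)
        return {lab: sorted(members) for lab, members in sorted(out.items())}

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    @property
    def singleton_clades(self) -> list[str]:
        return [lab for lab, members in self.clades.items() if len(members) == 1]

    def members(self, clade: str) -> list[str]:
        return self.clades[clade]

    def relabeled(self) -> "CladePartition":
        """Canonical labels: size-descending, ties by smallest member id."""
        groups = sorted(
            self.clades.values(), key=lambda members: (-len(members), members[0])
        )
        labels = clade_labels(len(groups))
        assignment = {g: lab for lab, members in zip(labels, groups) for g in members}
        return CladePartition(assignment, self.outgroup_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, lab) for g, lab in sorted(self.assignment.items())]
        rows += [(g, "outgroup") for g in sorted(self.outgroup_ids)]
        return pd.DataFrame(rows, columns=["genome_id", "clade"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CladePartition":
        assignment = {
            r.genome_id: r.clade for r in df.itertuples(index=False) if r.clade != "outgroup"
        }
        outgroup = frozenset(df.loc[df["clade"] == "outgroup", "genome_id"])
        return cls(assignment, outgroup)


def ward_cluster(dm: DistanceMatrix, k: int, variant: str = "D2") -> CladePartition:
    """Cut a Ward-linkage tree of the dissimilarity matrix into exactly k clades.

    ``variant="D2"`` (default) applies the Ward update to the dissimilarities
    directly (equivalent to R hclust ward.D2); ``variant="D"`` reproduces
    ward.D by feeding the square roots of the dissimilarities through the same
    recursion.  Clades are labeled A, B, C, ... in decreasing size order with
    ties broken by the lexicographically smallest member.
    """
    n = len(dm.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if dm.n_missing:
        raise ValueError(
            f"distance matrix has {dm.n_missing} missing pair(s); "
            "impute or drop genomes before clustering"
        )
    condensed = squareform(dm.values, checks=False)
    if variant == "D":
        condensed = np.sqrt(condensed)
    elif variant != "D2":
        raise ValueError("variant must be 'D' or 'D2'")
    Z = linkage(condensed, method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    assignment = {g: str(c) for g, c in zip(dm.ids, flat)}
    return CladePartition(assignment).relabeled()


def consensus_partition(p1: CladePartition, p2: CladePartition) -> CladePartition:
    """Partition meet: genomes co-claded only if co-claded in both inputs."""
    if set(p1.assignment) != set(p2.assignment):
        raise ValueError("partitions cover different genome sets")
    assignment = {
        g: f"{p1.assignment[g]}&{p2.assignment[g]}" for g in p1.assignment
    }
    out = CladePartition(
        assignment, frozenset(p1.outgroup_ids | p2.outgroup_ids)
    ).relabeled()
    return out


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    pairwise: pd.DataFrame  # columns: group_1, group_2, pseudo_F, p_value, q_value


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(groups == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_among = ss_total - ss_within
    a = n_groups
    if ss_within == 0.0:  # perfect separation
        return np.inf
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def _one_test(
    d2: np.ndarray, groups: np.ndarray, n_groups: int, n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    observed = _pseudo_f(d2, groups, n_groups)
    exceed = 0
    work = groups.copy()
    for _ in range(n_permutations):
        rng.shuffle(work)
        if _pseudo_f(d2, work, n_groups) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return observed, p


def permanova(
    dm: DistanceMatrix,
    labels: CladePartition | dict[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA of a distance matrix against clade labels.

    Returns the overall pseudo-F and permutation p-value, plus all pairwise
    two-group tests with Benjamini-Hochberg corrected q-values.  The p-value
    convention is (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    assignment = labels.assignment if isinstance(labels, CladePartition) else dict(labels)
    ids = [g for g in dm.ids if g in assignment]
    if len(ids) < len(dm.ids):
        keep = [i for i, g in enumerate(dm.ids) if g in assignment]
        values = dm.values[np.ix_(keep, keep)]
    else:
        values = dm.values
    group_names = sorted(set(assignment[g] for g in ids))
    if len(group_names) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    code = {lab: i for i, lab in enumerate(group_names)}
    groups = np.array([code[assignment[g]] for g in ids])
    sizes = np.bincount(groups, minlength=len(group_names))
    if (sizes < 2).any():
        small = [group_names[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"every group needs >=2 members; too small: {small}")
    d2 = values**2
    rng = np.random.default_rng(seed)
    observed, p = _one_test(d2, groups, len(group_names), n_permutations, rng)

    rows = []
    for a, b in itertools.combinations(range(len(group_names)), 2):
        members = np.flatnonzero((groups == a) | (groups == b))
        sub = d2[np.ix_(members, members)]
        sub_groups = (groups[members] == b).astype(int)
        f_ab, p_ab = _one_test(sub, sub_groups, 2, n_permutations, rng)
        rows.append((group_names[a], group_names[b], f_ab, p_ab))
    pairwise = pd.DataFrame(rows, columns=["group_1", "group_2", "pseudo_F", "p_value"])
    if len(pairwise):
        pairwise["q_value"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    else:
        pairwise["q_value"] = []
    return PermanovaResult(observed, p, n_permutations, pairwise)


def silhouette_profile(
    dm: DistanceMatrix, k_range: range = range(2, 13), variant: str = "D2"
) -> pd.DataFrame:
    """Mean silhouette width of the Ward partition for each k, to guide the
    choice of the number of clades (which is a required user parameter)."""
    rows = []
    for k in k_range:
        if k >= len(dm.ids):
            break
        part = ward_cluster(dm, k, variant=variant)
        labels = [part.assignment[g] for g in dm.ids]
        score = silhouette_score(dm.values, labels, metric="precomputed")
        rows.append((k, float(score)))
    return pd.DataFrame(rows, columns=["k", "mean_silhouette"])
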