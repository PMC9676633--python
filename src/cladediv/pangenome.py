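"""Pangenome substrate: gene presence/absence matrices and genome distance matrices.

The presence/absence matrix (genomes x gene clusters) is the substrate for
clade delineation, marker mining and core-gene selection.  Distances between
genomes come either from gene content (Jaccard dissimilarity) or from an
externally computed average-nucleotide-identity (ANI) table.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PresenceAbsenceMatrix",
    "DistanceMatrix",
    "read_presence_absence",
    "jaccard_distance",
    "load_ani_matrix",
]

# ROARY's gene_presence_absence.csv carries 14 metadata columns before the
# per-genome columns; only the first three are needed here.
_ROARY_META_COLUMNS = 14


@dataclass
class PresenceAbsenceMatrix:
    """Binary genomes x gene-clusters table.

    Attributes
    ----------
    df : pandas.DataFrame
        Index = genome ids, columns = gene-cluster ids, values in {0, 1}.
    gene_names : dict
        Optional annotation mapping gene-cluster id -> gene name (the
        ROARY "Gene" column), used to resolve housekeeping genes.
    source_dialect : str
        ``"csv"`` (quoted ROARY dialect) or ``"rtab"``.
    """

    df: pd.DataFrame
    gene_names: dict[str, str] = field(default_factory=dict)
    source_dialect: str = "csv"

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate genome identifiers in presence/absence matrix")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate gene identifiers in presence/absence matrix")
        if self.df.shape[0] < 2 or self.df.shape[1] < 1:
            raise ValueError("need at least 2 genomes and 1 gene")
        values = self.df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence/absence cells must be 0 or 1")
        self.df = self.df.astype(np.int8)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.columns)

    def presence_fraction(self, gene_id: str, genomes: list[str] | None = None) -> float:
        col = self.df[gene_id]
        if genomes is not None:
            col = col.loc[genomes]
        return float(col.mean())


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with labels.

    Missing pairs (e.g. ANI comparisons below the alignment-length cutoff)
    are stored as NaN; downstream clustering refuses matrices with missing
    cells.
    """

    ids: list[str]
    values: np.ndarray
    metric_tag: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square and match ids")
        finite = ~np.isnan(self.values)
        if not np.allclose(
            np.where(finite & finite.T, self.values, 0.0),
            np.where(finite & finite.T, self.values.T, 0.0),
            atol=1e-12,
        ):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
                raise ValueError("distances must lie in [0, 1]")

    @property
    def n_missing(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric_tag: str = "other") -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels must be identical and ordered")
        return cls(list(df.index), df.to_numpy(dtype=float), metric_tag)


def _read_roary_csv(text: str) -> PresenceAbsenceMatrix:
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    genome_cols = list(df.columns[_ROARY_META_COLUMNS:])
    if not genome_cols:
        raise ValueError("no genome columns found after ROARY metadata columns")
    gene_ids = df.iloc[:, 0].tolist()
    gene_names = dict(zip(gene_ids, df["Gene"])) if "Gene" in df.columns else {}
    # non-empty cell = present; paralog-split entries still count once
    presence = (df[genome_cols] != "").astype(np.int8)
    presence.index = gene_ids
    return PresenceAbsenceMatrix(presence.T, gene_names=gene_names, source_dialect="csv")


def _read_rtab(text: str) -> PresenceAbsenceMatrix:
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0).T.astype(np.int8)
    df.index.name = None
    df.columns.name = None
    return PresenceAbsenceMatrix(df, source_dialect="rtab")


def read_presence_absence(path: str) -> PresenceAbsenceMatrix:
    """Read a ROARY gene_presence_absence table, auto-detecting the dialect.

    The quoted CSV dialect is recognized by its ``"Gene","Non-unique Gene
    name",...`` header; anything tab-separated is treated as Rtab (binary).
    """
    with open(path) as fh:
        text = fh.read()
    header = text.splitlines()[0] if text else ""
    if "\t" in header:
        return _read_rtab(text)
    return _read_roary_csv(text)


def write_rtab(pam: PresenceAbsenceMatrix, path: str) -> None:
    pam.df.T.to_csv(path, sep="\t", index_label="Gene")


def jaccard_distance(pam: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Jaccard dissimilarity between genomes' gene sets: 1 - |A∩B| / |A∪B|."""
    mat = pam.df.to_numpy(dtype=bool)
    empty = ~mat.any(axis=1)
    if empty.any():
        offenders = [g for g, e in zip(pam.genome_ids, empty) if e]
        raise ValueError(
            "Jaccard distance undefined for genomes with no genes present: "
            + ", ".join(offenders)
        )
    dm = squareform(pdist(mat, metric="jaccard"))
    return DistanceMatrix(pam.genome_ids, dm, metric_tag="jaccard")


def load_ani_matrix(
    pairs: pd.DataFrame,
    min_alignment_bp: int = 500_000,
) -> DistanceMatrix:
    """Build an ANI distance matrix from long-format pairwise records.

    ``pairs`` columns: id_i, id_j, identity (fraction in [0,1]),
    aln_length (bp).  Distance = 1 - identity.  Pairs whose alignment length
    does not exceed ``min_alignment_bp`` (strict) are marked missing.  The two
    directed values of a pair are averaged; a pair present in one direction
    only triggers a warning and is used as-is.
    """
    pairs = pairs.copy()
    pairs.columns = ["id_i", "id_j", "identity", "aln_length"]
    if ((pairs["identity"] < 0) | (pairs["identity"] > 1)).any():
        raise ValueError("ANI identity values must lie in [0, 1]")
    ids = sorted(set(pairs["id_i"]) | set(pairs["id_j"]))
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    acc = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    for row in pairs.itertuples(index=False):
        if row.id_i == row.id_j:
            continue
        if row.aln_length <= min_alignment_bp:
            continue  # strict "exceeded" rule
        i, j = index[row.id_i], index[row.id_j]
        d = 1.0 - float(row.identity)
        if np.isnan(acc[i, j]):
            acc[i, j] = 0.0
        acc[i, j] += d
        counts[i, j] += 1
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 0.0)
    n_oneway = 0
    for i in range(n):
        for j in range(i + 1, n):
            have_ij = counts[i, j] > 0
            have_ji = counts[j, i] > 0
            if have_ij and have_ji:
                d = (acc[i, j] / counts[i, j] + acc[j, i] / counts[j, i]) / 2.0
            elif have_ij or have_ji:
                n_oneway += 1
                d = acc[i, j] / counts[i, j] if have_ij else acc[j, i] / counts[j, i]
            else:
                continue
            values[i, j] = values[j, i] = d
    if n_oneway:
        warnings.warn(
            f"{n_oneway} genome pair(s) present in one direction only; "
            "using the single available value",
            stacklevel=2,
        )
    dm = DistanceMatrix(ids, values, metric_tag="ani_distance")
    if dm.n_missing:
        warnings.warn(
            f"{dm.n_missing} genome pair(s) missing after alignment-length "
            f"filter (> {min_alignment_bp} bp required)",
            stacklevel=2,
        )
    return dm
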