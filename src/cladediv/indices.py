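"""Divergence Rate Indices: log-ratio divergence of marker genes vs housekeeping.

Four indices quantify how fast clade-specific marker genes diverge relative
to a housekeeping baseline, per metagenomic sample:

* DRIc  = ln(M_E / M_H): clade level, SNP-per-base (M_E = median over the
  clade's markers, M_H = median over the 10 housekeeping genes)
* DRIg  = ln(M_G / M_H): gene level, SNP-per-base
* NDRIc = ln(mu_E / mu_H): clade level, dN/dS (mu_E = mean over the clade's
  markers with valid omega, mu_H = mean over housekeeping genes)
* NDRIg = ln(mu_G / mu_H): gene level, dN/dS

Zero handling: when the denominator (M_H or mu_H) is zero it is substituted
by the smallest nonzero baseline observed across the whole cohort (the
"global floor"); when numerator and denominator are both zero the index is
zero.  A zero numerator with nonzero denominator is flagged non-diverging and
carried as a most-negative-rank sentinel (-inf): it can never pass the
strict-positivity divergence filter but still participates in medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .markers import MarkerCatalog
from .profiling import CohortMetadata
from .variants import GeneVariantStats

__all__ = [
    "HousekeepingBaseline",
    "GlobalFloor",
    "IndexValue",
    "housekeeping_baseline",
    "compute_global_floor",
    "log_ratio_index",
    "sample_indices",
    "aggregate_global",
    "aggregate_population",
    "filter_diverging_markers",
    "validate_baselines",
]

NON_DIVERGING = float("-inf")  # numerator-zero sentinel


@dataclass
class HousekeepingBaseline:
    sample_id: str
    M_H: float   # median SNP-per-base over the housekeeping panel
    mu_H: float  # mean valid dN/dS over the housekeeping panel (NaN if none)
    n_hk_used: int


@dataclass
class GlobalFloor:
    """Smallest nonzero baselines across the cohort, used as zero substitutes."""

    min_MH: float
    min_muH: float


@dataclass
class IndexValue:
    value: float
    flag: str = "ok"  # ok | both_zero | floor_substituted | non_diverging | missing


def stats_to_frame(stats: list[GeneVariantStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.gene_id, s.snp_count, s.gene_length_bp, s.snp_per_base,
             s.dn, s.ds, s.omega, s.omega_valid)
            for s in stats
        ],
        columns=["sample_id", "gene_id", "snp_count", "length_bp", "snp_per_base",
                 "dn", "ds", "omega", "omega_valid"],
    )


def housekeeping_baseline(
    stats: pd.DataFrame, catalog: MarkerCatalog, sample_id: str
) -> HousekeepingBaseline:
    """M_H (median SNP-per-base) and mu_H (mean valid omega) for one sample."""
    sub = stats[(stats["sample_id"] == sample_id)
                & stats["gene_id"].isin(catalog.housekeeping)]
    if sub.empty:
        raise ValueError(f"sample {sample_id}: no housekeeping gene statistics")
    if len(sub) < 5:
        import warnings

        warnings.warn(
            f"sample {sample_id}: only {len(sub)} housekeeping genes observed",
            stacklevel=2,
        )
    m_h = float(sub["snp_per_base"].median())
    valid = sub[sub["omega_valid"].astype(bool)]
    mu_h = float(valid["omega"].mean()) if len(valid) else float("nan")
    return HousekeepingBaseline(sample_id, m_h, mu_h, int(len(sub)))


def compute_global_floor(baselines: list[HousekeepingBaseline]) -> GlobalFloor:
    mh = [b.M_H for b in baselines if b.M_H > 0]
    muh = [b.mu_H for b in baselines if not math.isnan(b.mu_H) and b.mu_H > 0]
    return GlobalFloor(
        min_MH=min(mh) if mh else float("nan"),
        min_muH=min(muh) if muh else float("nan"),
    )


def log_ratio_index(numerator: float, denominator: float, floor: float | None = None) -> IndexValue:
    """ln(numerator/denominator) under the cohort zero rules."""
    if numerator < 0 or denominator < 0:
        raise ValueError("rates must be non-negative")
    if numerator == 0 and denominator == 0:
        return IndexValue(0.0, "both_zero")
    if denominator == 0:
        if floor is None or not floor > 0:
            raise ValueError("denominator is zero and no positive floor is available")
        return IndexValue(math.log(numerator / floor), "floor_substituted")
    if numerator == 0:
        return IndexValue(NON_DIVERGING, "non_diverging")
    return IndexValue(math.log(numerator / denominator), "ok")


def _index_or_missing(num: float | None, den: float, floor: float) -> IndexValue:
    if num is None or (isinstance(num, float) and math.isnan(num)):
        return IndexValue(float("nan"), "missing")
    if math.isnan(den):
        return IndexValue(float("nan"), "missing")
    return log_ratio_index(num, den, floor)


def sample_indices(
    stats: pd.DataFrame,
    baseline: HousekeepingBaseline,
    catalog: MarkerCatalog,
    floor: GlobalFloor,
    include_core_control: bool = True,
) -> pd.DataFrame:
    """Index table rows for one sample.

    Gene-level rows (level="gene") carry DRIg/NDRIg for each marker gene
    observed in the sample; clade-level rows (level="clade") carry DRIc/NDRIc
    with M_E = median SNP-per-base and mu_E = mean valid omega over the
    clade's observed markers.  With ``include_core_control`` the random core
    gene panel is aggregated the same way under the pseudo-clade "control"
    (and per-gene rows with level="core").
    """
    sub = stats[stats["sample_id"] == baseline.sample_id].set_index("gene_id")
    rows: list[tuple] = []

    def add_gene_rows(genes: list[str], level: str, clade: str) -> None:
        for g in genes:
            if g not in sub.index:
                continue
            rec = sub.loc[g]
            dri = _index_or_missing(float(rec["snp_per_base"]), baseline.M_H, floor.min_MH)
            if bool(rec["omega_valid"]):
                ndri = _index_or_missing(float(rec["omega"]), baseline.mu_H, floor.min_muH)
            else:
                ndri = IndexValue(float("nan"), "missing")
            rows.append((baseline.sample_id, level, g, clade,
                         dri.value, dri.flag, ndri.value, ndri.flag))

    def add_set_row(genes: list[str], clade: str) -> None:
        observed = [g for g in genes if g in sub.index]
        if not observed:
            rows.append((baseline.sample_id, "clade", clade, clade,
                         float("nan"), "missing", float("nan"), "missing"))
            return
        block = sub.loc[observed]
        m_e = float(block["snp_per_base"].median())
        valid = block[block["omega_valid"].astype(bool)]
        mu_e = float(valid["omega"].mean()) if len(valid) else float("nan")
        dri = _index_or_missing(m_e, baseline.M_H, floor.min_MH)
        ndri = _index_or_missing(mu_e, baseline.mu_H, floor.min_muH)
        rows.append((baseline.sample_id, "clade", clade, clade,
                     dri.value, dri.flag, ndri.value, ndri.flag))

    for clade in catalog.clades:
        add_gene_rows(catalog.markers[clade], "gene", clade)
        add_set_row(catalog.markers[clade], clade)
    if include_core_control and catalog.core:
        add_gene_rows(catalog.core, "core", "control")
        add_set_row(catalog.core, "control")
    return pd.DataFrame(
        rows,
        columns=["sample_id", "level", "key", "clade",
                 "DRI", "DRI_flag", "NDRI", "NDRI_flag"],
    )


def _median_with_sentinels(values: pd.Series) -> float:
    """Rank-based median: NaN (missing) excluded, -inf sentinels participate."""
    v = values.dropna().to_numpy()
    if len(v) == 0:
        return float("nan")
    return float(np.median(v))


def _quantile(values: pd.Series, q: float) -> float:
    v = values.dropna().to_numpy()
    if len(v) == 0:
        return float("nan")
    # rank-based when the non-diverging sentinel is present (no arithmetic
    # on -inf), linear interpolation otherwise
    method = "lower" if np.isneginf(v).any() else "linear"
    return float(np.percentile(v, q, method=method))


def _aggregate(table: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    def agg(block: pd.DataFrame) -> pd.Series:
        dri = block["DRI"].dropna()
        ndri = block["NDRI"].dropna()
        return pd.Series({
            "median_DRI": _median_with_sentinels(block["DRI"]),
            "DRI_q25": _quantile(block["DRI"], 25),
            "DRI_q75": _quantile(block["DRI"], 75),
            "n_DRI": int(len(dri)),
            "median_NDRI": _median_with_sentinels(block["NDRI"]),
            "NDRI_q25": _quantile(block["NDRI"], 25),
            "NDRI_q75": _quantile(block["NDRI"], 75),
            "n_NDRI": int(len(ndri)),
        })

    out = table.groupby(group_cols, sort=True).apply(agg, include_groups=False)
    return out.reset_index()


def aggregate_global(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort-wide medians (with quartiles) per (level, key)."""
    return _aggregate(table, ["level", "key", "clade"])


def aggregate_population(table: pd.DataFrame, meta: CohortMetadata) -> pd.DataFrame:
    """Per-population medians (with quartiles) per (level, key)."""
    missing = set(table["sample_id"]) - set(meta.sample_ids)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    merged = table.merge(
        meta.df["population"], left_on="sample_id", right_index=True
    )
    return _aggregate(merged, ["population", "level", "key", "clade"])


def filter_diverging_markers(global_table: pd.DataFrame) -> pd.DataFrame:
    """Marker genes with strictly positive global DRIg and NDRIg, by clade."""
    genes = global_table[global_table["level"] == "gene"]
    keep = genes[(genes["median_DRI"] > 0) & (genes["median_NDRI"] > 0)]
    out = keep[["clade", "key", "median_DRI", "median_NDRI"]].rename(
        columns={"key": "gene_id", "median_DRI": "global_DRIg", "median_NDRI": "global_NDRIg"}
    )
    return out.sort_values(["clade", "gene_id"]).reset_index(drop=True)


def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return float("nan"), float("nan"), "too_few_samples"
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), "zero_variance"
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # near-constant inputs
        r, p = pearsonr(x, y)
    if math.isnan(r):
        return float("nan"), float("nan"), "undefined"
    return float(r), float(p), ""


def validate_baselines(
    baselines: list[HousekeepingBaseline],
    manifests: pd.DataFrame,
    gene_table: pd.DataFrame | None = None,
    prevalence: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Coverage-bias screen: Pearson correlations of the housekeeping
    baselines against metagenome length and species abundance (and of gene
    prevalence against global DRIg/NDRIg when supplied).

    The design expectation is *no* significant correlation; any p <= alpha is
    flagged as a potential coverage bias.
    """
    if len(baselines) < 3:
        raise ValueError("need at least 3 samples to validate baselines")
    bl = pd.DataFrame(
        {
            "sample_id": [b.sample_id for b in baselines],
            "M_H": [b.M_H for b in baselines],
            "mu_H": [b.mu_H for b in baselines],
        }
    ).merge(manifests, on="sample_id")
    rows = []
    targets = [("metagenome_size_bp", "metagenome_length")]
    if "species_relative_abundance" in bl.columns:
        targets.append(("species_relative_abundance", "species_abundance"))
    for col, label in targets:
        for metric in ("M_H", "mu_H"):
            r, p, note = _corr(bl[metric].to_numpy(), bl[col].to_numpy())
            rows.append((metric, label, r, p, note))
    if gene_table is not None and prevalence:
        genes = gene_table[gene_table["level"] == "gene"]
        prev = genes["key"].map(prevalence)
        for metric in ("median_DRI", "median_NDRI"):
            vals = genes[metric].replace([np.inf, -np.inf], np.nan)
            r, p, note = _corr(prev.to_numpy(dtype=float), vals.to_numpy(dtype=float))
            rows.append((metric, "gene_prevalence", r, p, note))
    out = pd.DataFrame(rows, columns=["metric", "against", "r", "p", "note"])
    out["bias_warning"] = (out["p"] <= alpha) & out["note"].eq("")
    return out
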