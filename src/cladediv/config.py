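"""Run configuration: every stage threshold with its published default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline thresholds.

    Defaults are the analysis conventions this pipeline implements: marker
    presence >= 95% within clade with complete absence elsewhere; core genes
    at >= 95% panel presence with 500 randomly sampled controls; marker hit
    at >= 0.5X depth; clade call at >= 50% of markers hit; variant filters
    depth >= 10 and QUAL strictly > 200; dN/dS validity window
    0.01 < dS < 2; ANI pairs kept only when alignment length > 500 kb;
    species-level gate at 1% relative abundance for variant analysis;
    PERMANOVA with 999 free label permutations at FDR < 0.001.
    """

    k_clades: int = 5
    ward_variant: str = "D2"
    marker_presence: float = 0.95
    core_fraction: float = 0.95
    n_core: int = 500
    min_marker_cov: float = 0.5
    clade_fraction: float = 0.5
    genome_size_bp: int = 3_000_000
    min_depth: int = 10
    min_qual: float = 200.0
    ds_min: float = 0.01
    ds_max: float = 2.0
    min_ani_alignment_bp: int = 500_000
    species_gate: float = 0.01
    permanova_permutations: int = 999
    fdr_alpha: float = 0.001
    mean_over_hit_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.marker_presence <= 1:
            raise ValueError("marker_presence must lie in (0, 1]")
        if not 0 < self.core_fraction <= 1:
            raise ValueError("core_fraction must lie in (0, 1]")
        if self.min_marker_cov < 0 or self.clade_fraction < 0 or self.clade_fraction > 1:
            raise ValueError("coverage/fraction thresholds out of domain")
        if self.min_depth < 0 or self.min_qual < 0:
            raise ValueError("variant filters must be non-negative")
        if not 0 < self.ds_min < self.ds_max:
            raise ValueError("need 0 < ds_min < ds_max")
        if self.ward_variant not in ("D", "D2"):
            raise ValueError("ward_variant must be 'D' or 'D2'")
        if self.permanova_permutations < 99:
            raise ValueError("permanova_permutations must be >= 99")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
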