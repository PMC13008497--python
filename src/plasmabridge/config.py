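"""Structured configuration for the bridging workflow.

Collects every threshold the pipeline actually uses — IQR multiplier,
iterative-scaling bound, assay scale-factor window, concordance q threshold
and correlation floor, enrichment FDR, CV fold count, seeds, quartile
convention — so a run is fully auditable from its manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class BridgeConfig:
    iqr_multiplier: float = 1.5
    sd_bound: float = 4.0
    max_iterations: int = 50
    scale_factor_low: float = 0.4
    scale_factor_high: float = 2.5
    q_threshold: float = 0.05
    r_floor: float = 0.0
    enrichment_fdr: float = 0.1
    cv_k: int = 5
    seed: int = 0
    quartile_method: str = "linear"
    ddof: int = 1
    class_threshold: float = 0.5
    pairing_halt_median_r: float = 0.2
    generalizability_tail_fraction: float = 0.05
    generalizability_spearman_floor: float = 0.8
    min_selected_proteins: int = 10

    def __post_init__(self) -> None:
        if self.iqr_multiplier < 0 or self.sd_bound <= 0:
            raise ValueError("iqr_multiplier must be ≥0 and sd_bound >0")
        if not 0 < self.scale_factor_low <= self.scale_factor_high:
            raise ValueError("scale-factor range must be ordered and positive")
        if not (0 < self.q_threshold <= 1 and 0 < self.enrichment_fdr <= 1):
            raise ValueError("q_threshold and enrichment_fdr must lie in (0, 1]")
        if self.cv_k < 2:
            raise ValueError("cv_k must be ≥ 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "BridgeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
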