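"""Pipeline configuration with the study's documented thresholds as defaults."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    groups: tuple[str, ...] = ("ZY", "4C", "16C", "IVP")
    reference: str = "VO"
    replicates: int = 4

    # simulation
    genome_chroms: int = 2
    genome_length: int = 150_000
    genome_gc: float = 0.5
    amplifiable_range: tuple[int, int] = (50, 1500)
    noise_sd: float = 0.2
    dye_bias: float = 0.1
    dmr_fraction: float = 0.05
    effect_size: float = 1.0

    # preprocessing
    sd_multiplier: float = 4.0
    intensity_floor: float = 0.5
    loess_span: float = 0.3
    quantile_mode: str = "quantile"

    # DMR calling
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    threshold_is_log2: bool = False

    # DEG filter
    deg_fc_threshold: float = 1.5
    deg_p_threshold: float = 0.05
    deg_fdr_threshold: float = 0.3

    # annotation
    percentile_bounds: tuple[float, float] = (20.0, 80.0)
    shore_max: int = 2000
    shelf_max: int = 4000
    promoter_tiers: tuple[int, int, int] = (1000, 5000, 50000)

    # validation
    conversion_threshold: float = 0.95
    spikein_min_delta_ct: float = 5.0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("groups", "amplifiable_range", "percentile_bounds", "promoter_tiers"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the canonical YAML form."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
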