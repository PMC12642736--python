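"""Pipeline constants and run configuration.

Every tunable threshold of the method lives here, once, so that the
computation modules never carry hard-coded magic numbers:

* ``percentile`` — within-individual z-score percentile above which a feature
  is retained for ranking.
* ``min_phased_reads`` / ``min_phased_fraction`` — read-support filters for
  the allelic-imbalance statistic.
* ``bin1_proportion`` — untreated-sample isoform proportion below which an
  isoform counts as "rare" for the rare-steady-state statistic.
* ``downsample_target`` / ``downsample_threshold`` — library depth at which
  probabilistic read downsampling kicks in, and the depth it aims for.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class Defaults:
    percentile: float = 99.5
    min_phased_reads: int = 10
    min_phased_fraction: float = 0.10
    bin1_proportion: float = 0.01
    downsample_target: int = 5_000_000
    downsample_threshold: int = 7_000_000


DEFAULTS = Defaults()


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run.

    Paths may be ``None`` for in-memory use; thresholds default to the
    method's standard values from :data:`DEFAULTS`.
    """

    counts: str | Path | None = None
    classification: str | Path | None = None
    output_dir: str | Path | None = None
    percentile: float = DEFAULTS.percentile
    min_phased_reads: int = DEFAULTS.min_phased_reads
    min_phased_fraction: float = DEFAULTS.min_phased_fraction
    bin1_proportion: float = DEFAULTS.bin1_proportion
    downsample: bool = True
    downsample_target: int = DEFAULTS.downsample_target
    downsample_threshold: int = DEFAULTS.downsample_threshold
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValidationError(f"percentile must be in (0, 100), got {self.percentile}")
        if self.min_phased_reads < 0:
            raise ValidationError("min_phased_reads must be >= 0")
        if not 0.0 <= self.min_phased_fraction <= 1.0:
            raise ValidationError("min_phased_fraction must be in [0, 1]")
        if not 0.0 < self.bin1_proportion < 1.0:
            raise ValidationError("bin1_proportion must be in (0, 1)")
        if self.downsample_target < 1 or self.downsample_threshold < 1:
            raise ValidationError("downsample target/threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword arguments override file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("counts", "classification", "output_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d
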