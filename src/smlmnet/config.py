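"""Pipeline configuration.

A single flat record of the tunable analysis parameters, loadable from a
YAML file.  Stage functions take these values explicitly; the config object
is how the CLI and :func:`smlmnet.pipeline.run_pipeline` carry them around.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = ["PipelineConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Invalid pipeline or simulation configuration."""


@dataclass
class PipelineConfig:
    #: proximity radius for the blink-merging fixpoint, nm
    merge_threshold_nm: float = 20.0
    #: proximity-graph radius for denoising and blob network features, nm
    network_proximity_nm: float = 50.0
    #: flat-kernel mean-shift bandwidth, nm
    meanshift_bandwidth_nm: float = 180.0
    #: basins with fewer nodes than this are discarded as noise
    min_blob_size: int = 5
    #: boundary tightness values at which volumes are reported
    shrink_factors: tuple = (0.0, 0.5, 1.0)
    #: representative blobs retained per cell for boundary analysis
    top_n_representative: int = 10
    #: X-means search range for the number of blob groups
    kmin: int = 1
    kmax: int = 10
    random_seed: int = 0
    #: uniform null replicates for the denoising degree threshold
    null_reps: int = 10
    #: null-degree quantile above which nodes are retained
    retain_quantile: float = 0.95
    #: moving-average window (frames) for fiducial drift smoothing
    drift_window_frames: int = 50
    drift_correction: bool = True
    #: cluster blobs separately per condition (the default) or jointly
    cluster_per_condition: bool = True

    def validate(self) -> "PipelineConfig":
        if self.merge_threshold_nm <= 0:
            raise ConfigurationError("merge_threshold_nm must be > 0")
        if self.network_proximity_nm <= 0:
            raise ConfigurationError("network_proximity_nm must be > 0")
        if self.meanshift_bandwidth_nm <= 0:
            raise ConfigurationError("meanshift_bandwidth_nm must be > 0")
        if self.min_blob_size < 1:
            raise ConfigurationError("min_blob_size must be >= 1")
        if not all(0.0 <= s <= 1.0 for s in self.shrink_factors):
            raise ConfigurationError("shrink factors must lie in [0, 1]")
        if not (1 <= self.kmin <= self.kmax):
            raise ConfigurationError(
                f"require 1 <= kmin <= kmax, got kmin={self.kmin}, kmax={self.kmax}")
        if not (0.0 < self.retain_quantile < 1.0):
            raise ConfigurationError("retain_quantile must be in (0, 1)")
        if self.null_reps < 1:
            raise ConfigurationError("null_reps must be >= 1")
        if self.top_n_representative < 0:
            raise ConfigurationError("top_n_representative must be >= 0")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shrink_factors"] = list(self.shrink_factors)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "shrink_factors" in raw:
            raw["shrink_factors"] = tuple(raw["shrink_factors"])
        return cls(**raw).validate()
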