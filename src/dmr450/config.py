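"""Pipeline configuration: every analysis threshold in one declarative place.

Defaults are the thresholds the analysis is defined by: detection p 0.01
failing in >90% of samples, differential FDR < 0.001, per-pair |Δβ| > 0.2,
reference unmethylated mean β < 0.3, de novo frequency ≥ 40%, region
merging at FDR < 0.05 within 50 bp with ≥ 2 probes, top 500 regions.
Unknown keys in a config file are rejected outright.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    # input paths (unused fields may stay None when stages are driven in-memory)
    beta_path: str | None = None
    detection_p_path: str | None = None
    manifest_path: str | None = None
    sheet_path: str | None = None
    track_paths: dict[str, str] = field(default_factory=dict)
    outdir: str = "results"

    # mode
    design: str = "paired"  # paired | two_group
    de_novo_mode: str = "paired"  # paired | unpaired
    region_direction: str = "hyper"  # hyper | hypo | both
    harmonize_chrom: bool = False

    # probe filtering
    detect_p_cut: float = 0.01
    fail_fraction: float = 0.90
    drop_cross_reactive: bool = True
    drop_snp_proximal: bool = True

    # differential testing / classification
    fdr_diff: float = 0.001
    delta_cut: float = 0.2
    beta_ref_cut: float = 0.3
    freq_cut: float = 0.40
    tumor_beta_cut: float = 0.2
    autosomes_only: bool = True

    # regions
    region_fdr_cut: float = 0.05
    gap_bp: int = 50
    min_probes: int = 2
    top_n: int = 500
    n_perm: int = 1000

    seed: int = 0

    def validate(self) -> "PipelineConfig":
        fractions = {
            "detect_p_cut": self.detect_p_cut,
            "fail_fraction": self.fail_fraction,
            "fdr_diff": self.fdr_diff,
            "delta_cut": self.delta_cut,
            "beta_ref_cut": self.beta_ref_cut,
            "freq_cut": self.freq_cut,
            "tumor_beta_cut": self.tumor_beta_cut,
            "region_fdr_cut": self.region_fdr_cut,
        }
        for name, v in fractions.items():
            if not (0 <= v <= 1):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.gap_bp < 0:
            raise ConfigError("gap_bp must be >= 0")
        if self.min_probes < 1:
            raise ConfigError("min_probes must be >= 1")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if self.design not in ("paired", "two_group"):
            raise ConfigError(f"unknown design {self.design!r}")
        if self.de_novo_mode not in ("paired", "unpaired"):
            raise ConfigError(f"unknown de_novo_mode {self.de_novo_mode!r}")
        if self.region_direction not in ("hyper", "hypo", "both"):
            raise ConfigError(f"unknown region_direction {self.region_direction!r}")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Digest of the analysis parameters (paths and outdir excluded, so
        the same analysis written elsewhere reproduces the same hash)."""
        d = self.to_dict()
        for key in ("beta_path", "detection_p_path", "manifest_path",
                    "sheet_path", "track_paths", "outdir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]
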