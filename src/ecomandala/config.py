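"""Run configuration with strict (unknown-key-rejecting) YAML schema.

Defaults reproduce the validated analysis settings exactly: transfer
entropy with history length 1 and a kernel radius of 0.5 normalized units;
power-law fits with a KS-scanned xmin for abundances and a fixed xmin (the
minimum positive value) for transfer-entropy values; n_min = 8 tail points;
between-phylum Dp pairs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass
class TEParams:
    history: int = 1
    kernel_width: float = 0.5

    def __post_init__(self) -> None:
        if self.history < 1:
            raise ConfigError(f"te.history must be >= 1, got {self.history}")
        if self.kernel_width <= 0:
            raise ConfigError(f"te.kernel_width must be > 0, got {self.kernel_width}")


@dataclass
class FitParams:
    n_min: int = 8
    family_threshold: float = 2.0
    abundance_xmin_policy: str = "ks_scan"
    te_xmin_policy: str = "fixed"
    #: "pooled": fit epsilon to all (OTU, time) abundance observations;
    #: "otu_means": fit to per-OTU time-mean abundances instead.
    abundance_pooling: str = "pooled"

    def __post_init__(self) -> None:
        for name in ("abundance_xmin_policy", "te_xmin_policy"):
            val = getattr(self, name)
            if val not in ("fixed", "ks_scan"):
                raise ConfigError(f"fits.{name} must be 'fixed' or 'ks_scan', got {val!r}")
        if self.abundance_pooling not in ("pooled", "otu_means"):
            raise ConfigError(
                f"fits.abundance_pooling must be 'pooled' or 'otu_means', "
                f"got {self.abundance_pooling!r}"
            )
        if self.n_min < 2:
            raise ConfigError(f"fits.n_min must be >= 2, got {self.n_min}")


@dataclass
class PhyloParams:
    pair_set: str = "between"

    def __post_init__(self) -> None:
        if self.pair_set not in ("between", "all_others"):
            raise ConfigError(
                f"phylo.pair_set must be 'between' or 'all_others', got {self.pair_set!r}"
            )


@dataclass
class SiteInput:
    abundance: str
    site_id: str
    habitat: str
    taxonomy: str | None = None  # falls back to RunConfig.taxonomy


@dataclass
class PipelineConfig:
    """Method parameters shared by library entry points (no I/O fields)."""

    te: TEParams = field(default_factory=TEParams)
    fits: FitParams = field(default_factory=FitParams)
    phylo: PhyloParams = field(default_factory=PhyloParams)


@dataclass
class RunConfig(PipelineConfig):
    """Full CLI run configuration: inputs (files or synth block) + outputs."""

    sites: list[SiteInput] = field(default_factory=list)
    taxonomy: str | None = None
    synth: dict[str, Any] | None = None
    out_dir: str = "ecomandala_out"
    seed: int = 0
    figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sites and self.synth:
            raise ConfigError("config must give either file inputs or a synth block, not both")


def _from_dict(cls, data: dict, prefix: str = ""):
    """Build a dataclass from a nested dict, rejecting unknown keys by name."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {prefix or cls.__name__}, got {data!r}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = [k for k in data if k not in fields]
    if unknown:
        raise ConfigError(f"unknown config key {prefix + unknown[0]!r}")
    kwargs = {}
    nested = {"te": TEParams, "fits": FitParams, "phylo": PhyloParams}
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = _from_dict(nested[key], value, prefix=f"{key}.")
        elif key == "sites" and isinstance(value, list):
            kwargs[key] = [_from_dict(SiteInput, s, prefix="sites.") for s in value]
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_from_dict(data: dict) -> RunConfig:
    return _from_dict(RunConfig, data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"no such config file: {p}")
    with open(p) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_to_dict(config: RunConfig | PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def config_hash(config: RunConfig | PipelineConfig) -> str:
    """Stable short hash of the configuration, recorded in run manifests."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
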