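"""Run configuration: validation, defaults, and input resolution.

A run is described by a YAML (or already-parsed mapping) document.  Either
``network`` + ``attributes`` paths or a ``synthetic`` block must be given;
everything else has defaults.  Unknown keys are rejected so typos fail
loudly before any computation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["RunConfig", "RasConfig", "validate_config", "load_config",
           "load_inputs"]


class RasConfig(BaseModel):
    """Pathway case-study block: signal source and declared upstream genes."""

    model_config = ConfigDict(extra="forbid")

    source: str
    upstream: list[str] = []


class RunConfig(BaseModel):
    """Validated run configuration with defaults applied."""

    model_config = ConfigDict(extra="forbid")

    network: Path | None = None
    attributes: Path | None = None
    synthetic: dict[str, Any] | None = None
    seed: int = 0
    q_threshold: float = 0.05
    tie_tolerance: float = 0.0
    tissues: list[str] = []
    compartment_terms: dict[str, str] = {}
    exclusion_sets: dict[str, list[str]] = {}
    ras: RasConfig | None = None
    outdir: Path | None = None

    @field_validator("seed")
    @classmethod
    def _seed_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be a non-negative integer")
        return v

    @field_validator("q_threshold")
    @classmethod
    def _q_in_range(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("q_threshold must lie in (0, 1]")
        return v


def validate_config(raw: Mapping[str, Any]) -> RunConfig:
    """Validate a raw configuration mapping into a :class:`RunConfig`.

    Referenced input paths must exist; exactly one of file inputs or a
    synthetic block must describe the data source.
    """
    cfg = RunConfig.model_validate(dict(raw))
    if cfg.synthetic is None:
        if cfg.network is None or cfg.attributes is None:
            raise ValueError(
                "config must provide either network+attributes paths or a "
                "synthetic block")
        for name in ("network", "attributes"):
            path = getattr(cfg, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config document must be a mapping")
    return validate_config(raw)


def load_inputs(config: RunConfig | Mapping[str, Any]):
    """Resolve a config into (network, attribute table, validated config).

    A synthetic block generates the dataset in memory; otherwise the edge
    list and attribute table are read from the configured paths.
    """
    from .attributes import read_attribute_table
    from .network import load_edge_list
    from .synthetic import SyntheticConfig, generate_dataset

    if not isinstance(config, RunConfig):
        config = validate_config(config)
    if config.synthetic is not None:
        block = dict(config.synthetic)
        block.setdefault("seed", config.seed)
        dataset = generate_dataset(SyntheticConfig(**block))
        return dataset.network, dataset.attributes, config
    network = load_edge_list(config.network)
    attributes = read_attribute_table(config.attributes)
    return network, attributes, config
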