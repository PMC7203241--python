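"""Run configuration: validated schema, file loading, provenance hashing.

One config file drives the whole pipeline. Unknown keys are rejected so a
typo cannot silently disable a stage. The canonical JSON form of the config
is hashed and the hash is stamped into every output table's header comment.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError
from .fcs_io import ChannelMap, TransformSpec
from .gating import GateConfig
from .phenotyping import LineageRuleset


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelCfg(_Model):
    detector: str
    marker: str = ""
    role: Literal[
        "scatter_area", "scatter_height", "side_scatter",
        "viability", "marker", "ignore",
    ]


class TransformCfg(_Model):
    kind: Literal["identity", "arcsinh"] = "identity"
    cofactor: float = 150.0
    channels: Optional[list[str]] = None

    @field_validator("cofactor")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("cofactor must be positive")
        return v


class SingletCfg(_Model):
    enabled: bool = True
    band_factor: float = 2.5
    fit_intercept: bool = False


class DensityGateCfg(_Model):
    enabled: bool = True
    fallback_quantile: Optional[float] = None


class GatesCfg(_Model):
    singlet: SingletCfg = SingletCfg()
    debris: DensityGateCfg = DensityGateCfg()
    live: DensityGateCfg = DensityGateCfg()


class KdeCfg(_Model):
    bandwidth_multiplier: float = 1.0
    grid_points: int = 512


class ThresholdsCfg(_Model):
    quantile: float = 0.99
    clean_fmos: bool = True
    fmo: dict[str, str] = Field(default_factory=dict)  # marker -> file name
    overrides: dict[str, float] = Field(default_factory=dict)


class FilterCfg(_Model):
    min_percent: float = 0.5
    min_count: Optional[int] = None
    constraints: dict[str, int] = Field(default_factory=dict)


class RuleCfg(_Model):
    field: Literal["lineage", "subset", "resident"]
    label: str
    constraints: dict[str, int]


class LineageCfg(_Model):
    default_label: str = "unknown"
    rules: list[RuleCfg] = Field(default_factory=list)


class StatsCfg(_Model):
    correlation_method: Literal["pearson", "spearman"] = "pearson"
    ttest_variant: Literal["welch", "student"] = "welch"
    fdr_method: Literal["bh", "by", "bonferroni"] = "bh"
    enable_fdr: bool = False
    alpha: float = 0.05


class PathsCfg(_Model):
    samples: str = "samples"
    fmos: Optional[str] = None
    metadata: Optional[str] = None
    outcome: Optional[str] = None
    output: str = "out"
    manual: Optional[str] = None  # manual-gating comparison table


class SyntheticCfg(_Model):
    n_samples: int = 10
    n_events: int = 50_000
    n_fmo_events: int = 20_000
    doublet_frac: float = 0.05
    debris_frac: float = 0.10
    dead_frac: float = 0.10
    dirichlet_concentration: float = 250.0
    seed: int = 0
    write_fcs_files: bool = True


class RunConfig(_Model):
    paths: PathsCfg = PathsCfg()
    channels: list[ChannelCfg] = Field(default_factory=list)
    transform: TransformCfg = TransformCfg()
    gates: GatesCfg = GatesCfg()
    kde: KdeCfg = KdeCfg()
    thresholds: ThresholdsCfg = ThresholdsCfg()
    filter: FilterCfg = FilterCfg()
    lineage: LineageCfg = LineageCfg()
    stats: StatsCfg = StatsCfg()
    synthetic: SyntheticCfg = SyntheticCfg()

    def channel_map(self) -> ChannelMap:
        if not self.channels:
            raise ConfigurationError("config declares no channels")
        return ChannelMap.from_entries(
            (c.detector, c.marker or c.detector, c.role) for c in self.channels
        )

    def transform_spec(self) -> TransformSpec:
        return TransformSpec(
            kind=self.transform.kind,
            cofactor=self.transform.cofactor,
            channels=None
            if self.transform.channels is None
            else tuple(self.transform.channels),
        )

    def gate_config(self) -> GateConfig:
        return GateConfig(
            singlet_enabled=self.gates.singlet.enabled,
            band_factor=self.gates.singlet.band_factor,
            fit_intercept=self.gates.singlet.fit_intercept,
            debris_enabled=self.gates.debris.enabled,
            debris_fallback_quantile=self.gates.debris.fallback_quantile,
            live_enabled=self.gates.live.enabled,
            live_fallback_quantile=self.gates.live.fallback_quantile,
            bandwidth_multiplier=self.kde.bandwidth_multiplier,
            grid_points=self.kde.grid_points,
        )

    def ruleset(self) -> LineageRuleset:
        return LineageRuleset.from_config(
            [r.model_dump() for r in self.lineage.rules],
            default_label=self.lineage.default_label,
        )

    def lineage_order(self) -> list[str]:
        return self.ruleset().lineage_order

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def dump_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    """Load a YAML or TOML run config; validation errors name the field."""
    path = Path(path)
    try:
        if path.suffix in (".toml", ".tml"):
            import tomllib

            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigurationError(f"invalid config {path}:\n{exc}") from exc


def write_table(df: pd.DataFrame, path, config_hash: str, index: bool = False) -> None:
    """Write a CSV with the config hash as a header comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index)
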