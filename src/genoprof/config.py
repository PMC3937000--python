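"""Run configuration: one plain key-value (YAML) file drives the whole
pipeline.  Unknown keys are rejected so typos fail loudly, and every
effective value (defaults included) is logged at run time."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .insilico_gp import DistortionSpec, MobilityModel, Primer
from .lineage_sim import TreeSpec

logger = logging.getLogger(__name__)

__all__ = ["PcrConfig", "TggeConfig", "AnalysisConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class PcrConfig:
    primer_name: str = "Pfm12"
    primer: str = "AGAACGCGCCTG"
    max_mismatch: int = 6
    anchor3: int = 3
    min_len: int = 500
    max_len: int = 1500
    n_bands: int | None = None

    def primer_obj(self) -> Primer:
        return Primer(self.primer_name, self.primer)


@dataclass(frozen=True)
class TggeConfig:
    tm_window: int = 500
    tm_denaturant_offset: float = 20.0
    mobility_lmin: int = 100
    mobility_lmax: int = 3000
    mob_scale_range: tuple[float, float] = (0.9, 1.1)
    mob_offset_range: tuple[float, float] = (-0.05, 0.05)
    temp_scale_range: tuple[float, float] = (0.95, 1.05)
    temp_offset_range: tuple[float, float] = (-2.0, 2.0)
    sigma_mobility: float = 0.005
    sigma_temp: float = 0.005

    def mobility_model(self) -> MobilityModel:
        return MobilityModel(self.mobility_lmin, self.mobility_lmax)

    def distortion(self) -> DistortionSpec:
        return DistortionSpec(
            tuple(self.mob_scale_range), tuple(self.mob_offset_range),
            tuple(self.temp_scale_range), tuple(self.temp_offset_range),
            self.sigma_mobility, self.sigma_temp,
        )


@dataclass(frozen=True)
class AnalysisConfig:
    ward_variant: str = "ward.d"
    replicate_mode: str = "mean"  # "mean" or "single"
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.ward_variant not in ("ward.d", "ward.d2"):
            raise ValueError(f"unknown ward_variant {self.ward_variant!r}")
        if self.replicate_mode not in ("mean", "single"):
            raise ValueError(f"unknown replicate_mode {self.replicate_mode!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    tree: TreeSpec = field(default_factory=TreeSpec)
    pcr: PcrConfig = field(default_factory=PcrConfig)
    tgge: TggeConfig = field(default_factory=TggeConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            coerced[f.name] = v
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a key-value mapping")
    unknown = set(raw) - {"tree", "pcr", "tgge", "analysis", "seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = RunConfig(
        tree=_build(TreeSpec, raw.get("tree", {}), "tree"),
        pcr=_build(PcrConfig, raw.get("pcr", {}), "pcr"),
        tgge=_build(TggeConfig, raw.get("tgge", {}), "tgge"),
        analysis=_build(AnalysisConfig, raw.get("analysis", {}), "analysis"),
        seed=int(raw.get("seed", 0)),
    )
    log_config(cfg)
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for block in d.values():
        if isinstance(block, dict):
            for k, v in block.items():
                if isinstance(v, tuple):
                    block[k] = list(v)
    return d


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def log_config(cfg: RunConfig) -> None:
    for line in yaml.safe_dump(config_to_dict(cfg), sort_keys=False).splitlines():
        logger.info("config: %s", line)
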