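"""Pipeline configuration.

One declarative YAML file holds every numeric threshold and simulation
parameter; CLI flags override it, and the effective configuration is
echoed into the output directory of each run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import simulate
from .quantify import NoiseModel
from .simulate import CommunityTemplate


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, simulation parameters and run settings.

    Defaults equal the assay's published thresholds (dominant >0.50,
    intermediate lower bound 0.10, B2 exclusivity >0.90, probe LOD 0.001,
    subtraction LOD 0.15, CFU class bounds 1e6/1e7).
    """

    dominant_threshold: float = 0.50
    intermediate_low: float = 0.10
    exclusivity_threshold: float = 0.90
    probe_lod_fraction: float = 0.001
    subtraction_lod_fraction: float = 0.15
    cfu_low_bound: float = 1e6
    cfu_high_bound: float = 1e7
    log10_measurement_sd: float = 0.03
    templates: tuple[CommunityTemplate, ...] = field(
        default_factory=lambda: tuple(simulate.default_templates())
    )
    n_per_template: int = 30
    seed: int = 0
    outdir: str = "colitype_out"

    def __post_init__(self) -> None:
        for name in (
            "dominant_threshold",
            "intermediate_low",
            "exclusivity_threshold",
            "probe_lod_fraction",
            "subtraction_lod_fraction",
        ):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if not self.intermediate_low < self.dominant_threshold:
            raise ValueError("intermediate_low must be below dominant_threshold")
        if not self.probe_lod_fraction < self.subtraction_lod_fraction:
            raise ValueError(
                "probe_lod_fraction must be below subtraction_lod_fraction"
            )
        if not 0 < self.cfu_low_bound < self.cfu_high_bound:
            raise ValueError("CFU class bounds must satisfy 0 < low < high")
        if self.log10_measurement_sd < 0:
            raise ValueError("log10_measurement_sd must be >= 0")
        if self.n_per_template < 1:
            raise ValueError("n_per_template must be >= 1")

    def noise_model(self) -> NoiseModel:
        return NoiseModel(
            log10_measurement_sd=self.log10_measurement_sd,
            probe_lod_fraction=self.probe_lod_fraction,
            subtraction_lod_fraction=self.subtraction_lod_fraction,
        )

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["templates"] = [dataclasses.asdict(t) for t in self.templates]
        for t in data["templates"]:
            t["composition_mean"] = list(t["composition_mean"])
            t["host_species"] = list(t["host_species"])
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "templates" in data and data["templates"] is not None:
            data["templates"] = tuple(
                t if isinstance(t, CommunityTemplate) else CommunityTemplate(
                    enterocolitype_label=t["enterocolitype_label"],
                    composition_mean=tuple(t["composition_mean"]),
                    composition_concentration=t.get(
                        "composition_concentration", simulate.DEFAULT_CONCENTRATION
                    ),
                    log10_cfu_mean=t.get("log10_cfu_mean", 7.0),
                    log10_cfu_sd=t.get("log10_cfu_sd", 0.5),
                    host_species=tuple(t.get("host_species", ("human",))),
                    a1_fraction_of_a=t.get("a1_fraction_of_a", 0.5),
                )
                for t in data["templates"]
            )
        return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)
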