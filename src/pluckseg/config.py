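"""Run configuration: a validated YAML schema tying the pipeline together.

Unknown keys are rejected so typos fail loudly; every command echoes the
validated configuration beside its outputs as a reproducibility record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .context import DEFAULT_N_RAYS, DEFAULT_RADII, StencilSpec, make_star_stencil
from .errors import ConfigError
from .features import DecompositionConfig
from .model import VariantConfig

__all__ = ["RunConfig", "StencilConfig", "FeatureConfig", "load_config"]


class StencilConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_rays: int = DEFAULT_N_RAYS
    radii: list[int] = Field(default_factory=lambda: list(DEFAULT_RADII))

    def build(self) -> StencilSpec:
        return make_star_stencil(self.n_rays, tuple(self.radii))


class FeatureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    levels: int = 3
    subsample_factor: int = 20
    square_details: bool = True

    def build(self) -> DecompositionConfig:
        return DecompositionConfig(self.levels, self.subsample_factor, self.square_details)


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 30
    grid_height: int = 180
    grid_width: int = 60
    liver_missing_prob: float = 0.02
    noise_sd: float = 9.0
    specular_rate: float = 0.004


class RunConfig(BaseModel):
    """Top-level configuration for every pipeline command."""

    model_config = ConfigDict(extra="forbid")

    variant: Literal["ac", "ac+ic", "waac", "waac+ic"] = "ac"
    iterations: int = 5
    m_w: int = 32
    per_class_samples: int = 1600
    hidden_units: int = 20
    l2: float = 1e-3
    max_iter: int = 500
    tol: float = 1e-5
    first_iteration_plain_ac: bool = True
    seed: int = 0
    folds: int = 10
    log_level: str = "INFO"
    stencil: StencilConfig = Field(default_factory=StencilConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)

    def variant_config(self) -> VariantConfig:
        return VariantConfig.from_name(
            self.variant,
            T=self.iterations,
            m_w=self.m_w,
            per_class_samples=self.per_class_samples,
            stencil=self.stencil.build(),
            seed=self.seed,
            first_iteration_plain_ac=self.first_iteration_plain_ac,
            hidden_units=self.hidden_units,
            l2=self.l2,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def decomposition(self) -> DecompositionConfig:
        return self.features.build()


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration field(s): {fields}") from exc
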