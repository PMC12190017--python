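"""Run configuration: strict YAML/JSON validation for the CLI.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running with defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .pipeline import PipelineParams
from .profiles import DEFAULT_PROTOCOLS, ProtocolProfile
from .segment import SegmentationParams, SpotParams
from .stains import StainModel


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    resolution_um_per_px: float
    numerical_aperture: float | None = None
    n_focus_layers: int = 1
    layer_step_um: float = 0.0
    blur_sigma_um: float = 0.0
    fade_factor: float = 1.0
    focus_instability: float = 0.0
    calibrated: bool = True


class SegmentationConfig(_Strict):
    expected_radius_um: float = 4.0
    min_area_um2: float = 20.0
    max_area_um2: float = 300.0
    min_solidity: float = 0.85
    min_circularity: float = 0.6
    otsu_offset: float = 0.0
    min_threshold: float = 0.12
    min_mean_concentration: float = 0.18
    smooth_sigma_frac: float = 0.25
    seed_min_distance_frac: float = 0.8


class SpotConfig(_Strict):
    diameter_um: float = 0.9
    diameter_range_um: tuple[float, float] = (0.6, 1.2)
    n_scales: int = 4
    threshold_her2: float = 0.15
    threshold_cep17: float = 0.12


class InclusionConfig(_Strict):
    min_her2: int = 2
    min_cep17: int = 2
    aneusomy_mode: bool = False
    name: str = "standard"


class RunConfig(_Strict):
    """Top-level configuration for all subcommands."""

    seed: int = 0
    out_dir: str = "her2ish-out"
    verbosity: str = "INFO"
    stain_model: str | None = None  # path to a stain-model JSON; None = default
    protocols: dict[str, ProtocolConfig] = Field(default_factory=dict)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    spots: SpotConfig = Field(default_factory=SpotConfig)
    inclusion: InclusionConfig = Field(default_factory=InclusionConfig)

    def protocol_profiles(self) -> dict[str, ProtocolProfile]:
        """Shipped defaults overlaid with any configured protocols."""
        out = dict(DEFAULT_PROTOCOLS)
        for name, pc in self.protocols.items():
            out[name] = ProtocolProfile(name=name, **pc.model_dump())
        return out

    def pipeline_params(self) -> PipelineParams:
        stain = (
            StainModel.from_json(self.stain_model)
            if self.stain_model
            else StainModel.default()
        )
        seg = SegmentationParams(**self.segmentation.model_dump())
        sp = self.spots.model_dump()
        sp["diameter_range_um"] = tuple(sp["diameter_range_um"])
        return PipelineParams(stain=stain, segmentation=seg, spots=SpotParams(**sp))


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON config; ``None`` gives defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)
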