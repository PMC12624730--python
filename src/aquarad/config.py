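"""Validated run configuration (YAML or JSON).

Unknown keys are rejected outright — a typo in a config file should fail the
run, not silently fall back to a default.  The fully defaulted effective
configuration is echoed next to every pipeline's outputs for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .reflectance import ReflectanceParams
from .spectra import WavelengthGrid

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    start: float = 390.0
    stop: float = 880.0
    step: float = 1.0

    def to_grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.start, self.stop, self.step)


class ReflectanceConfig(_Strict):
    rho: float = 0.02
    panel_correction: float = 1.01
    panel_reflectance: float = 0.99

    def to_params(self) -> ReflectanceParams:
        return ReflectanceParams(
            rho=self.rho,
            panel_correction=self.panel_correction,
            panel_reflectance=self.panel_reflectance,
        )


class CampaignConfig(_Strict):
    n_sites: int = Field(6, ge=2)
    n_stations: int = Field(31, ge=2)
    noise_sd_fraction: float = Field(0.01, ge=0.0)
    backscatter_level: float = Field(0.01, gt=0.0)


class MetricsConfig(_Strict):
    nrmse_norm: str = "range"  # "range" | "mean"
    sid_eps: float = 1e-8


class RunConfig(_Strict):
    grid: GridConfig = Field(default_factory=GridConfig)
    reflectance: ReflectanceConfig = Field(default_factory=ReflectanceConfig)
    campaign: CampaignConfig = Field(default_factory=CampaignConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    band_sets: List[str] = Field(default_factory=lambda: ["pace_oci", "olci"])
    seed: int = 0

    def echo(self, path: Union[str, Path]) -> None:
        """Write the fully defaulted effective configuration as YAML."""
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True, default_flow_style=False)
        )


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load and validate a YAML/JSON config; None gives all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    ) or {}
    return RunConfig.model_validate(data)
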