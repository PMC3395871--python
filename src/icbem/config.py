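"""Run configuration: a validated, unit-explicit YAML schema.

Every physical quantity carries its unit in the key name (``*_angstrom``),
and unknown keys are rejected so that typos fail loudly before any
computation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SphereParams(_StrictModel):
    n_theta: int = 32
    n_phi: int = 32


class ChannelParams(_StrictModel):
    pore_radius_angstrom: float = 6.5
    membrane_width_angstrom: float = 30.0
    corner_radius_angstrom: float = 5.0
    lateral_extent_angstrom: float = 40.0
    n_tiles_target: int = 860


class RingParams(_StrictModel):
    n_dipoles: int = 20
    z_positions_angstrom: tuple[float, float] = (-3.0, 3.0)
    radial_depth_neg_angstrom: float = 2.0
    axial_extra_pos_angstrom: float = 2.0
    dipole_charge_e: float = 1.0
    disabled_indices: list[int] = Field(default_factory=list)


class EvaluationParams(_StrictModel):
    kind: Literal["total_potential", "reaction_potential"] = "total_potential"
    points_angstrom: list[tuple[float, float, float]] = Field(default_factory=list)


class MapParams(_StrictModel):
    plane_z_angstrom: float = 0.0
    grid_half_width_angstrom: float = 5.5
    grid_n: int = 41
    mask_radius_angstrom: float | None = None


class RunConfig(_StrictModel):
    """Top-level run description (see the README for a worked example)."""

    scenario: Literal[
        "sphere", "channel", "channel-dipoles", "channel-dipoles-broken"
    ]
    solver: Literal["icc", "iter", "both"] = "icc"
    delta_stop: float = 1e-4
    max_iter: int = 1000
    accurate_quadrature: bool = True
    sphere: SphereParams = Field(default_factory=SphereParams)
    channel: ChannelParams = Field(default_factory=ChannelParams)
    rings: RingParams = Field(default_factory=RingParams)
    ion_position_angstrom: tuple[float, float, float] | None = None
    evaluation: EvaluationParams | None = None
    map: MapParams | None = None
    out_dir: str = "icbem-out"
    # all current computations are deterministic; reserved for future use
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid config {path}: {locs}") from exc
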