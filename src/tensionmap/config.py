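"""Validated pipeline configuration.

All physical quantities carry explicit units: internal computation uses
ns (lifetimes), s (times), um (lengths), L (volumes), Hz (rates), pN
(forces) and Pa/kPa (stress). Force thresholds may be written as bare
numbers (pN) or as strings with a unit ("7 pN"). Unknown keys are
rejected, so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["PipelineConfig", "SensorForces", "parse_config", "parse_force_pN"]

_FORCE_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(pN)?\s*$")


def parse_force_pN(value) -> float:
    """Parse a force given as a number or a '<x> pN' string into pN."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _FORCE_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse force {value!r}; expected e.g. '7 pN'")
    return float(m.group(1))


class SensorForces(BaseModel):
    """Force thresholds (pN) of the calibrated sensor modules.

    Defaults are the upper design points of the published linker
    calibrations: F40 responds at 1-6 pN, HP (villin headpiece) at 6-8 pN,
    HPst (stabilised headpiece) at 9-11 pN. The HP threshold of 7 pN is
    the value used for stress estimates.
    """

    model_config = ConfigDict(extra="forbid")

    F40: float = 3.5
    HP: float = 7.0
    HPst: float = 10.0

    @field_validator("F40", "HP", "HPst", mode="before")
    @classmethod
    def _force(cls, v):
        return parse_force_pN(v)


class PipelineConfig(BaseModel):
    """Schema-validated parameters of the full analysis pipeline."""

    model_config = ConfigDict(extra="forbid")

    # FLIM
    tail_start: float | None = Field(
        default=None,
        description="tail-fit start (ns); None = histogram peak + 0.5 ns",
    )
    max_rel_error: float = Field(
        default=0.05, gt=0,
        description="QC cut-off on the lifetime relative standard error",
    )
    fit_background: bool = False
    tau_nofret: float | None = Field(default=None, gt=0)
    tau_fret: float | None = Field(default=None, gt=0)

    # FCS
    model_id: str = "T+T+3D+3D"
    s: float = Field(default=5.0, gt=0, description="detection-volume axis ratio")
    d_ref: float = Field(
        default=414.0, gt=0,
        description="reference-dye diffusion coefficient (um^2/s)",
    )

    # imaging
    pixel_dwell: float = Field(default=50e-6, gt=0, description="PT (s)")
    saturation_rate: float = Field(default=2e6, gt=0, description="Hz")

    # stress
    forces: SensorForces = Field(default_factory=SensorForces)
    membrane_single_plane_area: float = Field(default=0.63, gt=0)
    n_membranes: int = Field(default=2, gt=0)
    ruffle_factor: float = Field(default=2.0, gt=0)

    # run control
    seed: int = 0
    input_dir: Path | None = None
    output_dir: Path | None = None

    @field_validator("model_id")
    @classmethod
    def _model(cls, v):
        from .fcs import MODEL_IDS

        if v not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        return v


def parse_config(path) -> PipelineConfig:
    """Load and validate a YAML or JSON configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return PipelineConfig.model_validate(raw)
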