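"""Run configuration: schema-validated JSON with geometry, materials, leads,
target, solver and steering sections. Unknown keys are rejected; the fully
defaulted configuration is embedded in every output for provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .exceptions import ConfigurationError
from .materials import material_table
from .phantom import DEFAULT_SHELLS, LeadLayout, PhantomConfig
from .solver import SolverOptions
from .steering import DEFAULT_SEED


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Section):
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    shells: list[tuple[str, float]] = [tuple(s) for s in DEFAULT_SHELLS]
    z_length: float = 40.0
    transverse_pad: float = 0.25
    disc_band_period: float | None = None
    disc_band_width: float = 2.0

    def to_phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            spacing=self.spacing,
            shells=tuple((str(n), float(r)) for n, r in self.shells),
            z_length=self.z_length,
            transverse_pad=self.transverse_pad,
            disc_band_period=self.disc_band_period,
            disc_band_width=self.disc_band_width,
        )


class MaterialsSection(_Section):
    #: per-label conductivity overrides, isotropic value or (x, y, z) triple
    overrides: dict[str, float | tuple[float, float, float]] = {}

    def to_table(self):
        table = material_table()
        return table.replace(**self.overrides) if self.overrides else table


class LeadsSection(_Section):
    separation: float = 3.0  # between lead axes; clinically one of 3 settings
    depth_y: float = 8.0  # dorsal epidural depth of both leads
    stagger: float = 0.0  # lead-B longitudinal offset, multiples of 0.5 mm
    n_electrodes: int = 8
    electrode_length: float = 2.0
    pitch: float = 4.0
    lead_radius: float = 0.6
    tip_margin: float = 1.0
    z_center: float = 0.0

    @field_validator("stagger")
    @classmethod
    def _half_mm(cls, v: float) -> float:
        if abs(v / 0.5 - round(v / 0.5)) > 1e-9:
            raise ValueError(f"stagger must be a multiple of 0.5 mm, got {v}")
        return v

    def to_layout(self) -> LeadLayout:
        return LeadLayout(
            centers=(
                (-self.separation / 2.0, self.depth_y),
                (self.separation / 2.0, self.depth_y),
            ),
            stagger=self.stagger,
            n_electrodes=self.n_electrodes,
            electrode_length=self.electrode_length,
            pitch=self.pitch,
            lead_radius=self.lead_radius,
            tip_margin=self.tip_margin,
            z_center=self.z_center,
        )


class TargetSection(_Section):
    center: tuple[float, float, float] = (0.0, 3.0, 0.0)
    diameter: float = 0.5
    length: float | None = None  # defaults to the diameter


class SolverSection(_Section):
    method: Literal["auto", "direct", "cg"] = "auto"
    rtol: float = 1e-10
    direct_limit: int = 60_000
    ilu_drop_tol: float = 1e-4
    ilu_fill_factor: float = 10.0

    def to_options(self) -> SolverOptions:
        return SolverOptions(
            method=self.method,
            rtol=self.rtol,
            direct_limit=self.direct_limit,
            ilu_drop_tol=self.ilu_drop_tol,
            ilu_fill_factor=self.ilu_fill_factor,
        )


class SteeringSection(_Section):
    variant: Literal["two_sided", "floating", "one_sided"] = "two_sided"
    floating: list[str] = []  # user-declared disconnected electrodes
    k_active: int = 8  # clinical cap: k/2 nearest electrodes per lead
    ground_max: int = 4  # one-sided: largest enumerated ground set
    n_starts: int = 5  # one-sided: SLSQP multistarts per combination


class RunConfig(_Section):
    geometry: GeometrySection = GeometrySection()
    materials: MaterialsSection = MaterialsSection()
    leads: LeadsSection = LeadsSection()
    target: TargetSection = TargetSection()
    solver: SolverSection = SolverSection()
    steering: SteeringSection = SteeringSection()
    seed: int = DEFAULT_SEED  # drives the one-sided multistart sampling

    def config_hash(self) -> str:
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}")
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc))
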