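"""Run configuration: typed, YAML-round-trippable, validated.

A configuration names a geometry preset (cylinder benchmark, healthy
forearm, forearm with an end-to-side fistula), the discretisation, the
inlet drive, the capillary-bed parameters and the schedule.  All physical
quantities carry explicit SI unit suffixes in their key names.

Bed resistance and capacitance default to test-scale values; science runs
should set them explicitly for the vasculature being modelled.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from .units import UnitSystem, compute_tau

__all__ = ["UnitsConfig", "SimulationConfig", "reference_units", "validate_config"]


class UnitsConfig(BaseModel):
    dx_m: float = Field(gt=0)
    dt_s: float = Field(gt=0)
    rho_kg_per_m3: float = Field(default=1000.0, gt=0)
    nu_m2_per_s: float = Field(default=4.0e-6, gt=0)

    def to_units(self) -> UnitSystem:
        return UnitSystem(dx=self.dx_m, dt=self.dt_s,
                          rho_ref=self.rho_kg_per_m3, nu_phys=self.nu_m2_per_s)


def reference_units() -> UnitsConfig:
    """The reference discretisation: dx = 50 um, dt = 3 us, blood at
    rho = 1000 kg/m^3 and nu = 4.0e-6 m^2/s, giving tau = 0.5144."""
    return UnitsConfig(dx_m=50e-6, dt_s=3e-6)


class SimulationConfig(BaseModel):
    preset: Literal["cylinder-poiseuille", "forearm-healthy", "forearm-fistula"]
    units: UnitsConfig
    lambda_magic: float = Field(default=1.0 / 12.0, gt=0)
    total_steps: int = Field(ge=0)
    coupling_interval: int = Field(default=500, ge=1)
    warmup_s: float = Field(default=0.8, ge=0)
    cadence: int = Field(default=100, ge=1)

    inlet_waveform: Literal["steady", "brachial"] = "steady"
    inlet_mean_velocity_m_per_s: float = 0.042
    outlet_pressure_pa: float = 0.0

    bed_resistance_pa_s_per_m3: float = 1e9
    bed_capacitance_m3_per_pa: float = 0.0
    force_gain: float = 1.0
    v_d_form: Literal["flow_weighted", "plain_sum"] = "flow_weighted"

    # geometry knobs
    cylinder_radius_m: float = 2.0e-3
    cylinder_length_m: float = 4.0e-3
    dilate_cephalic_factor: float | None = None  # post-maturation dilation

    seed: int = 0

    @model_validator(mode="after")
    def _stable(self) -> "SimulationConfig":
        tau = compute_tau(self.units.to_units())
        if tau <= 0.5:
            raise ValueError(f"resolved tau = {tau} must exceed 1/2")
        return self

    # --- YAML round trip ------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def validate_config(config: SimulationConfig) -> tuple[bool, list[str]]:
    """Check run invariants; returns (ok, human-readable report lines)."""
    lines: list[str] = []
    ok = True
    units = config.units.to_units()
    tau = compute_tau(units)
    lines.append(f"relaxation time tau = {tau:.4f} (lattice viscosity {units.nu_lat:.4g})")
    if tau <= 0.5:
        ok = False
        lines.append("ERROR: tau must exceed 1/2 for stability")
    u_lat = units.velocity_to_lattice(config.inlet_mean_velocity_m_per_s)
    lines.append(f"mean inlet lattice speed = {u_lat:.4f}")
    if abs(u_lat) >= 0.3:
        ok = False
        lines.append("ERROR: mean inlet lattice speed >= 0.3 (instability threshold)")
    elif abs(u_lat) >= 0.1:
        lines.append("WARNING: mean inlet lattice speed >= 0.1; accuracy degrades")
    if config.inlet_waveform == "brachial":
        peak_lat = units.velocity_to_lattice(0.286)
        lines.append(f"peak inlet lattice speed = {peak_lat:.4f}")
        if peak_lat >= 0.3:
            ok = False
            lines.append("ERROR: waveform peak exceeds the instability threshold "
                         "at this discretisation")
    warmup_steps = config.warmup_s / units.dt
    lines.append(f"warm-up covers {warmup_steps:.0f} steps of {config.total_steps}")
    if config.preset != "cylinder-poiseuille":
        lines.append(f"coupling every {config.coupling_interval} steps "
                     f"({config.coupling_interval * units.dt * 1e3:.3g} ms)")
    lines.append("config OK" if ok else "config INVALID")
    return ok, lines
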