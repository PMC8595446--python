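"""Build and execute configured runs.

Presets wire the fixtures to the boundary stack: the cylinder benchmark is
a single instance with a parabolic-weight inlet and a pressure outlet; the
forearm presets build the coupled arterial/venous pair with a single
capillary bed over the wrist openings (and, for the fistula preset, the
1:1 anastomosis pairing with the distal cephalic feeders sealed).

Every opening receives exactly one role: the arterial inlet is
waveform-driven, arterial terminal outlets are pressure outlets with bed
feedback forcing, venous capillary inlets are coupling-driven velocity
inlets, and venous trunk outlets are pressure outlets.
"""

from __future__ import annotations

import json
from pathlib import Path

from .boundaries import InletWaveform, brachial_waveform
from .config import SimulationConfig
from .coupling import BedOpening, CapillaryBed, CouplingSchedule, FistulaPairing
from .fixtures import cylinder_tree, forearm_trees
from .geometry import apply_fistula, dilate_vessel, voxelize_vessels
from .observables import write_timeseries
from .simulation import (CoupledRunner, InletAssignment, Instance,
                         OutletAssignment, run_single)

__all__ = ["build_single", "build_coupled", "run_simulation",
           "run_coupled_simulation"]


def _waveform(config: SimulationConfig) -> InletWaveform:
    if config.inlet_waveform == "brachial":
        return brachial_waveform(warmup_duration=config.warmup_s)
    return InletWaveform.steady(config.inlet_mean_velocity_m_per_s,
                                warmup_duration=config.warmup_s)


def build_single(config: SimulationConfig) -> Instance:
    if config.preset != "cylinder-poiseuille":
        raise ValueError(f"preset {config.preset!r} is a coupled run")
    units = config.units.to_units()
    tree = cylinder_tree(radius=config.cylinder_radius_m,
                         length=config.cylinder_length_m)
    domain = voxelize_vessels(tree, units.dx)
    return Instance(
        domain, units, lambda_magic=config.lambda_magic,
        inlets=[InletAssignment(patch_id="inlet", mode="waveform",
                                waveform=_waveform(config),
                                profile_radius=config.cylinder_radius_m)],
        outlets=[OutletAssignment(patch_id="outlet",
                                  pressure_pa=config.outlet_pressure_pa)],
        name="cylinder")


def build_coupled(config: SimulationConfig) -> CoupledRunner:
    if config.preset not in ("forearm-healthy", "forearm-fistula"):
        raise ValueError(f"preset {config.preset!r} is not a coupled run")
    units = config.units.to_units()
    fixture = forearm_trees(dx=units.dx)
    arterial_tree, venous_tree = fixture.arterial, fixture.venous
    pairing = None
    bed_venous_ids = list(fixture.venous_inlets)
    extra_art_outlets: list[OutletAssignment] = []
    extra_ven_inlets: list[InletAssignment] = []

    if config.preset == "forearm-fistula":
        spec = fixture.anastomosis
        if config.dilate_cephalic_factor:
            venous_tree = dilate_vessel(venous_tree, "cephalic",
                                        config.dilate_cephalic_factor)
        arterial_tree, venous_tree, fmap = apply_fistula(
            arterial_tree, venous_tree, spec)
        pairing = FistulaPairing(pairs=fmap.pairs)
        bed_venous_ids = [v for v in bed_venous_ids
                          if v not in venous_tree.sealed_openings]
        extra_art_outlets.append(OutletAssignment(
            patch_id=spec.arterial_opening_id,
            pressure_pa=config.outlet_pressure_pa))
        extra_ven_inlets.append(InletAssignment(
            patch_id=spec.venous_opening_id, mode="coupled"))

    art_domain = voxelize_vessels(arterial_tree, units.dx)
    ven_domain = voxelize_vessels(venous_tree, units.dx)

    arterial = Instance(
        art_domain, units, lambda_magic=config.lambda_magic,
        inlets=[InletAssignment(patch_id=fixture.arterial_inlet,
                                mode="waveform", waveform=_waveform(config))],
        outlets=[OutletAssignment(patch_id=o, pressure_pa=config.outlet_pressure_pa,
                                  forced=True, force_gain=config.force_gain)
                 for o in fixture.arterial_outlets] + extra_art_outlets,
        name="arterial")
    venous = Instance(
        ven_domain, units, lambda_magic=config.lambda_magic,
        inlets=[InletAssignment(patch_id=v, mode="coupled")
                for v in bed_venous_ids] + extra_ven_inlets,
        outlets=[OutletAssignment(patch_id=o, pressure_pa=config.outlet_pressure_pa)
                 for o in fixture.venous_outlets],
        name="venous")

    bed = CapillaryBed(
        id="wrist_bed",
        arterial=[BedOpening(id=o, area=art_domain.opening(o).area)
                  for o in fixture.arterial_outlets],
        venous=[BedOpening(id=v, area=ven_domain.opening(v).area)
                for v in bed_venous_ids],
        R=config.bed_resistance_pa_s_per_m3,
        C_bar=config.bed_capacitance_m3_per_pa)

    conserve = config.preset == "forearm-fistula" and bool(config.dilate_cephalic_factor)
    return CoupledRunner(
        arterial=arterial, venous=venous, beds=[bed],
        schedule=CouplingSchedule(interval=config.coupling_interval),
        fistula=pairing, fistula_conserve_flow=conserve,
        v_d_form=config.v_d_form)


def _write_records(records: dict, out_dir: Path, prefix: str = "") -> None:
    for pid, rec in records.items():
        write_timeseries(rec, out_dir / f"{prefix}{pid}.csv")


def run_simulation(config: SimulationConfig, output_dir: str | Path) -> dict:
    """Single-instance run; probe CSVs are written to ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    instance = build_single(config)
    records = run_single(instance, config.total_steps,
                         probe_openings=["inlet", "outlet"],
                         cadence=config.cadence)
    _write_records(records, out)
    return {"records": records, "instance": instance}


def run_coupled_simulation(config: SimulationConfig, output_dir: str | Path) -> dict:
    """Coupled arterial/venous run; probe CSVs and a conservation report are
    written to ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = build_coupled(config)
    art_probes = [a.patch_id for a in runner.arterial.inlets] + \
                 [o.patch_id for o in runner.arterial.outlets]
    ven_probes = [o.patch_id for o in runner.venous.outlets]
    result = runner.run(config.total_steps, arterial_probes=art_probes,
                        venous_probes=ven_probes, cadence=config.cadence)
    _write_records(result["arterial"], out, prefix="arterial_")
    _write_records(result["venous"], out, prefix="venous_")
    (out / "conservation.json").write_text(
        json.dumps(result["conservation"], indent=2))
    result["runner"] = runner
    return result
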