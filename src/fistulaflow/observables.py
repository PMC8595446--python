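"""Flow probes, time series, field output and domain/waveform persistence.

Everything emitted from this module is in SI units; lattice-unit values
never leave it.  Flow probes are axis-aligned lattice planes (the synthetic
fixtures are built axis-aligned so plane integration is exact).  Field
snapshots are written as legacy-ASCII VTK STRUCTURED_POINTS files with
velocity (m/s) and pressure (Pa); domains persist to an HDF5 container with
a versioned schema string; time series and waveforms are header-ed CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .boundaries import InletWaveform
from .geometry import OpeningPatch, VoxelDomain
from .lattice import FluidState
from .units import UnitSystem

__all__ = [
    "PlaneProbe",
    "TimeSeriesRecord",
    "probe_from_opening",
    "probe_from_plane",
    "measure_plane_flow",
    "write_fields",
    "read_fields",
    "write_timeseries",
    "read_timeseries",
    "write_waveform",
    "read_waveform",
    "write_domain",
    "read_domain",
]

DOMAIN_SCHEMA = "fistulaflow-domain-1"


@dataclass
class PlaneProbe:
    """Axis-aligned lattice plane through a vessel or opening."""

    id: str
    sites: np.ndarray  # fluid site indices in the plane
    unit_normal: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise ValueError(f"probe {self.id!r} intersects no fluid sites")


@dataclass
class TimeSeriesRecord:
    """Samples of one probe: (step, time s, Q m^3/s, mean velocity m/s, area m^2)."""

    probe_id: str
    steps: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    flows: list[float] = field(default_factory=list)
    mean_velocities: list[float] = field(default_factory=list)
    ref_flows: list[float] = field(default_factory=list)  # reference-density mass flow
    area: float = 0.0

    def append(self, step: int, time: float, flow: float, mean_velocity: float,
               ref_flow: float | None = None) -> None:
        if self.steps and step <= self.steps[-1]:
            raise ValueError("time series steps must be monotone increasing")
        self.steps.append(step)
        self.times.append(time)
        self.flows.append(flow)
        self.mean_velocities.append(mean_velocity)
        self.ref_flows.append(flow if ref_flow is None else ref_flow)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": self.steps, "time_s": self.times,
            "flow_m3_per_s": self.flows,
            "mean_velocity_m_per_s": self.mean_velocities,
            "ref_density_flow_m3_per_s": self.ref_flows,
            "area_m2": self.area,
        })


def probe_from_opening(domain: VoxelDomain, opening_id: str) -> PlaneProbe:
    p = domain.opening(opening_id)
    return PlaneProbe(id=opening_id, sites=p.sites, unit_normal=p.unit_normal)


def probe_from_plane(domain: VoxelDomain, probe_id: str, axis: int,
                     index: int, positive: bool = True) -> PlaneProbe:
    sites = np.where(domain.fluid_ijk[:, axis] == index)[0]
    normal = np.zeros(3)
    normal[axis] = 1.0 if positive else -1.0
    return PlaneProbe(id=probe_id, sites=sites, unit_normal=normal)


def measure_plane_flow(state: FluidState, probe: PlaneProbe,
                       units: UnitSystem, density_weighted: bool = False) -> float:
    """Flow through the probe plane, m^3/s.

    Default is the volumetric flux Q = sum u.n dx^2.  With
    ``density_weighted`` the local lattice density enters the sum and the
    result is the mass flow divided by the reference density — the quantity
    a quasi-incompressible lattice Boltzmann run conserves exactly.  The two
    differ by the pseudo-compressible density variation along the vessel,
    which is negligible at fine time steps but visible at coarse desk-scale
    discretisations.
    """
    u_n = state.u[probe.sites] @ probe.unit_normal
    if density_weighted:
        u_n = u_n * state.rho[probe.sites]
    return units.flow_to_physical(float(u_n.sum()))


def opening_mean_velocity(state: FluidState, patch: OpeningPatch,
                          units: UnitSystem) -> float:
    """Mean outward-normal velocity over an opening patch, m/s."""
    u_n = state.u[patch.sites] @ patch.unit_normal
    return units.velocity_to_physical(float(u_n.mean()))


# --------------------------------------------------------------------------
# VTK structured-points output (legacy ASCII)
# --------------------------------------------------------------------------

def write_fields(state: FluidState, domain: VoxelDomain, units: UnitSystem,
                 path: str | Path) -> Path:
    """Write velocity (m/s) and pressure (Pa) as a legacy-ASCII VTK file.

    Solid voxels carry zeros.  The arrays round-trip bit-compatibly through
    :func:`read_fields` (repr-exact ASCII floats).
    """
    path = Path(path)
    nx, ny, nz = domain.shape
    vel = np.zeros((nx, ny, nz, 3))
    prs = np.zeros((nx, ny, nz))
    ijk = domain.fluid_ijk
    vel[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = units.velocity_to_physical(state.u)
    prs[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = units.pressure_of_density(state.rho)
    try:
        with path.open("w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write(f"fistulaflow fields step={state.step}\n")
            fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
            ox, oy, oz = (float(v) for v in domain.origin)
            sp = float(domain.spacing)
            fh.write(f"ORIGIN {ox!r} {oy!r} {oz!r}\n")
            fh.write(f"SPACING {sp!r} {sp!r} {sp!r}\n")
            fh.write(f"POINT_DATA {nx * ny * nz}\n")
            fh.write("SCALARS pressure_pa double 1\nLOOKUP_TABLE default\n")
            # VTK structured points iterate x fastest
            for v in prs.transpose(2, 1, 0).ravel():
                fh.write(f"{float(v)!r}\n")
            fh.write("VECTORS velocity_m_per_s double\n")
            for v in vel.transpose(2, 1, 0, 3).reshape(-1, 3):
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
    except OSError as exc:
        raise OSError(f"failed writing VTK fields to {path}: {exc}") from exc
    return path


def read_fields(path: str | Path) -> dict:
    """Read back a field file written by :func:`write_fields`."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    dims = tuple(int(x) for x in lines[4].split()[1:])
    origin = np.array([float(x) for x in lines[5].split()[1:]])
    spacing = float(lines[6].split()[1])
    npts = dims[0] * dims[1] * dims[2]
    base = 10
    prs = np.array([float(x) for x in lines[base:base + npts]])
    vec_start = base + npts + 1
    vel = np.array([[float(x) for x in ln.split()]
                    for ln in lines[vec_start:vec_start + npts]])
    nx, ny, nz = dims
    return {
        "dimensions": dims, "origin": origin, "spacing": spacing,
        "pressure_pa": prs.reshape(nz, ny, nx).transpose(2, 1, 0),
        "velocity_m_per_s": vel.reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3),
    }


# --------------------------------------------------------------------------
# CSV time series and waveforms
# --------------------------------------------------------------------------

def write_timeseries(record: TimeSeriesRecord, path: str | Path) -> Path:
    path = Path(path)
    record.frame().to_csv(path, index=False, float_format="%.12e")
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"step", "time_s", "flow_m3_per_s"}
    if not required <= set(df.columns):
        raise ValueError(f"time series {path} missing columns {required - set(df.columns)}")
    if np.any(np.diff(df["step"].to_numpy()) <= 0):
        raise ValueError(f"time series {path} has non-monotone steps")
    return df


def write_waveform(waveform: InletWaveform, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_s": waveform.samples[:, 0],
        "velocity_m_per_s": waveform.samples[:, 1],
    }).to_csv(path, index=False, float_format="%.9e")
    return path


def read_waveform(path: str | Path, period: float | None = None,
                  warmup_duration: float = 0.8) -> InletWaveform:
    """Read a two-column (time_s, velocity_m_per_s) CSV; times must increase.

    Without an explicit ``period`` the waveform period is taken as the last
    sample time plus one sample interval.
    """
    df = pd.read_csv(path)
    cols = {"time_s", "velocity_m_per_s"}
    if not cols <= set(df.columns):
        raise ValueError(f"waveform {path} must have columns {sorted(cols)}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"waveform {path} has non-increasing times")
    if period is None:
        period = float(t[-1] + (t[-1] - t[0]) / max(len(t) - 1, 1))
    return InletWaveform(samples=df[["time_s", "velocity_m_per_s"]].to_numpy(),
                         period=period, warmup_duration=warmup_duration)


# --------------------------------------------------------------------------
# HDF5 domain container
# --------------------------------------------------------------------------

def write_domain(domain: VoxelDomain, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["schema"] = DOMAIN_SCHEMA
        h5.attrs["spacing_m"] = domain.spacing
        h5.attrs["origin_m"] = domain.origin
        h5.attrs["shape"] = domain.shape
        h5.create_dataset("site_type", data=domain.site_type, compression="gzip")
        h5.create_dataset("fluid_ijk", data=domain.fluid_ijk, compression="gzip")
        grp = h5.create_group("openings")
        for p in domain.openings:
            g = grp.create_group(p.id)
            g.attrs["role"] = p.role
            g.attrs["unit_normal"] = p.unit_normal
            g.attrs["area_m2"] = p.area
            g.attrs["mean_radius_m"] = p.mean_radius
            g.attrs["centre_m"] = p.centre
            g.create_dataset("sites", data=p.sites)
    return path


def read_domain(path: str | Path) -> VoxelDomain:
    with h5py.File(path, "r") as h5:
        if h5.attrs["schema"] != DOMAIN_SCHEMA:
            raise ValueError(f"unsupported domain schema {h5.attrs['schema']!r}")
        fluid_ijk = h5["fluid_ijk"][...]
        shape = tuple(int(s) for s in h5.attrs["shape"])
        index_grid = np.full(shape, -1, dtype=np.int64)
        index_grid[fluid_ijk[:, 0], fluid_ijk[:, 1], fluid_ijk[:, 2]] = \
            np.arange(len(fluid_ijk))
        openings = []
        for oid, g in h5["openings"].items():
            area = float(g.attrs["area_m2"])
            openings.append(OpeningPatch(
                id=oid, role=str(g.attrs["role"]), sites=g["sites"][...],
                unit_normal=np.asarray(g.attrs["unit_normal"]),
                area=area, mean_radius=float(g.attrs["mean_radius_m"]),
                centre=np.asarray(g.attrs["centre_m"])))
        return VoxelDomain(shape=shape, spacing=float(h5.attrs["spacing_m"]),
                           origin=np.asarray(h5.attrs["origin_m"]),
                           fluid_ijk=fluid_ijk, index_grid=index_grid,
                           openings=openings)
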