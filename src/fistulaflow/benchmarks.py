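"""Validation benchmarks.

``poiseuille_cylinder`` drives steady flow through a straight cylinder with
a parabolic-weight velocity inlet and a zero-pressure outlet, then compares
the axial velocity profile on a cross-sectional plane against the analytic
Hagen-Poiseuille parabola ``v(r) = 2 v_mean (1 - (r/R)^2)``.  Halving dx
(with dt scaled acoustically, keeping tau fixed) should shrink the L2
profile error roughly four-fold: the Bouzidi wall treatment is second-order
accurate on curved walls.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig, UnitsConfig
from .orchestrate import build_single
from .simulation import Instance, run_single

__all__ = ["poiseuille_cylinder", "profile_error"]

# reference physical setup: R = 2 mm, L = 4 mm, mean inlet speed 8 mm/s,
# blood viscosity 4e-6 m^2/s -> Re = v D / nu = 8
RADIUS = 2.0e-3
LENGTH = 4.0e-3
V_MEAN = 0.008
TAU_TARGET = 0.8  # lattice viscosity 0.1 at every resolution


def _units_for(sites_across: int) -> UnitsConfig:
    dx = 2.0 * RADIUS / sites_across
    nu_lat = (TAU_TARGET - 0.5) / 3.0
    dt = nu_lat * dx**2 / 4.0e-6
    return UnitsConfig(dx_m=dx, dt_s=dt)


def profile_error(instance: Instance, plane_fraction: float = 0.75) -> float:
    """L2 relative error of the axial velocity profile on one lattice plane.

    The analytic reference is the Hagen-Poiseuille parabola carrying the
    flow rate actually injected at the inlet (the imposed mean velocity
    times the discrete patch area): the steady profile downstream is set by
    the flow rate, and the voxelized cap area differs from pi R^2 by a
    perimeter term that is not a property of the flow solution.
    """
    domain = instance.domain
    units = instance.units
    q_in = V_MEAN * domain.opening("inlet").area
    v_mean = q_in / (np.pi * RADIUS**2)
    z_plane = plane_fraction * LENGTH
    k = int(round((z_plane - domain.origin[2]) / units.dx - 0.5))
    sites = np.where(domain.fluid_ijk[:, 2] == k)[0]
    centers = domain.site_centers(sites)
    r2 = centers[:, 0] ** 2 + centers[:, 1] ** 2
    v_sim = units.velocity_to_physical(instance.state.u[sites, 2])
    v_ana = 2.0 * v_mean * (1.0 - r2 / RADIUS**2)
    return float(np.linalg.norm(v_sim - v_ana) / np.linalg.norm(v_ana))


def poiseuille_cylinder(sites_across: int = 20, total_steps: int = 3000) -> dict:
    """Run the benchmark at the requested resolution and measure the error."""
    config = SimulationConfig(
        preset="cylinder-poiseuille", units=_units_for(sites_across),
        total_steps=total_steps, warmup_s=0.0, inlet_waveform="steady",
        inlet_mean_velocity_m_per_s=V_MEAN,
        cylinder_radius_m=RADIUS, cylinder_length_m=LENGTH)
    instance = build_single(config)
    records = run_single(instance, total_steps,
                         probe_openings=["inlet", "outlet"], cadence=500)
    q_in = -records["inlet"].flows[-1]
    q_out = records["outlet"].flows[-1]
    return {
        "sites_across": sites_across,
        "n_fluid": instance.domain.n_fluid,
        "l2_error": profile_error(instance),
        "q_in_m3_per_s": q_in,
        "q_out_m3_per_s": q_out,
        "mass_balance_error": abs(q_in - q_out) / abs(q_in),
        "instance": instance,
        "records": records,
    }
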