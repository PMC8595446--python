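import numpy as np
import pytest

from fistulaflow.boundaries import (InletWaveform, StabilityError,
                                    brachial_waveform, bouzidi_apply,
                                    dynamic_pressure_force,
                                    patch_interior_neighbors,
                                    poiseuille_weights,
                                    pressure_outlet_apply,
                                    velocity_inlet_apply)
from fistulaflow.fixtures import yjunction_tree
from fistulaflow.geometry import WallLinkSet, voxelize_vessels
from fistulaflow.lattice import FluidState, TRTParameters, equilibrium
from fistulaflow.simulation import (InletAssignment, Instance,
                                    OutletAssignment, run_single)
from fistulaflow.stencil import D3Q19
from fistulaflow.units import UnitSystem


# --------------------------------------------------------------------------
# waveform
# --------------------------------------------------------------------------

def test_waveform_rejects_nonincreasing_times():
    with pytest.raises(ValueError):
        InletWaveform(samples=np.array([[0.0, 0.1], [0.0, 0.2]]), period=1.0)


def test_warmup_ramp_reaches_unity():
    w = InletWaveform.steady(0.1, warmup_duration=0.8)
    assert w.value(0.0) == 0.0
    assert w.value(0.4) == pytest.approx(0.05)
    assert w.value(0.8) == pytest.approx(0.1)
    assert w.value(5.3) == pytest.approx(0.1)


def test_default_waveform_peak_and_mean():
    w = brachial_waveform()
    assert w.peak() == pytest.approx(0.286, abs=1e-9)
    assert w.mean() == pytest.approx(0.042, abs=1e-4)


def test_waveform_periodic_seam_continuous():
    w = brachial_waveform()
    eps = 1e-9
    assert abs(w.value(w.warmup_duration + w.period - eps)
               - w.value(w.warmup_duration + w.period + eps)) < 1e-6


# --------------------------------------------------------------------------
# weight map
# --------------------------------------------------------------------------

def test_poiseuille_weights_unit_mean_and_rim_decay(small_cylinder_domain):
    domain = small_cylinder_domain
    patch = domain.opening("inlet")
    wm = poiseuille_weights(domain, patch, radius=1.0e-3)
    assert wm.weights.mean() == pytest.approx(1.0, abs=1e-12)
    assert np.all(wm.weights >= 0)
    centers = domain.site_centers(patch.sites)
    r = np.hypot(centers[:, 0], centers[:, 1])
    assert wm.weights[np.argmax(r)] < wm.weights[np.argmin(r)]


# --------------------------------------------------------------------------
# opening reconstruction
# --------------------------------------------------------------------------

def test_velocity_inlet_imposes_target(small_cylinder_domain):
    domain = small_cylinder_domain
    patch = domain.opening("inlet")
    nb = patch_interior_neighbors(domain, patch)
    state = FluidState.at_rest(domain.n_fluid)
    u_t = np.tile([0.0, 0.0, 0.03], (len(patch.sites), 1))
    velocity_inlet_apply(state.f, patch, nb, u_t)
    c = D3Q19.velocities.astype(float)
    f = state.f[patch.sites]
    u = (f @ c) / f.sum(axis=1)[:, None]
    assert np.allclose(u, u_t, atol=1e-14)


def test_velocity_inlet_rejects_supersonic(small_cylinder_domain):
    domain = small_cylinder_domain
    patch = domain.opening("inlet")
    nb = patch_interior_neighbors(domain, patch)
    state = FluidState.at_rest(domain.n_fluid)
    with pytest.raises(StabilityError):
        velocity_inlet_apply(state.f, patch, nb,
                             np.tile([0.0, 0.0, 0.7], (len(patch.sites), 1)))


def test_pressure_outlet_fixes_density(small_cylinder_domain):
    domain = small_cylinder_domain
    patch = domain.opening("outlet")
    nb = patch_interior_neighbors(domain, patch)
    state = FluidState.at_rest(domain.n_fluid)
    pressure_outlet_apply(state.f, patch, nb, rho_target=1.002)
    assert np.allclose(state.f[patch.sites].sum(axis=1), 1.002, atol=1e-14)
    with pytest.raises(ValueError):
        pressure_outlet_apply(state.f, patch, nb, rho_target=-0.1)


# --------------------------------------------------------------------------
# Bouzidi walls
# --------------------------------------------------------------------------

def test_bouzidi_at_half_equals_halfway_bounce_back(rng):
    n = 40
    f_post = equilibrium(1.0 + 0.05 * rng.uniform(-1, 1, n),
                         0.05 * rng.uniform(-1, 1, (n, 3)))
    opp = D3Q19.opposite_index
    site = rng.integers(0, n, 30).astype(np.int64)
    direction = rng.integers(1, 19, 30).astype(np.int64)
    links = WallLinkSet(site=site, direction=direction, q=np.full(30, 0.5))
    src = np.full((n, 19), -1, dtype=np.int64)
    f_a = f_post.copy()
    bouzidi_apply(f_a, f_post, links, src)
    # half-way bounce-back: the reflected population is the post-collision
    # population that was heading into the wall
    assert np.allclose(f_a[site, opp[direction]], f_post[site, direction],
                       rtol=1e-15)


def test_rest_fluid_stays_at_rest_with_walls(small_cylinder_domain):
    units = UnitSystem(dx=2e-4, dt=1e-3)
    instance = Instance(
        small_cylinder_domain, units,
        inlets=[InletAssignment(patch_id="inlet", mode="waveform",
                                waveform=InletWaveform.steady(0.0, warmup_duration=0.0))],
        outlets=[OutletAssignment(patch_id="outlet", pressure_pa=0.0)])
    run_single(instance, 100, cadence=100)
    assert np.max(np.abs(instance.state.u)) < 1e-13


# --------------------------------------------------------------------------
# Guo forcing
# --------------------------------------------------------------------------

def test_uniform_force_accelerates_periodic_fluid(rng):
    """Momentum bookkeeping: bulk velocity grows by F/rho per step."""
    from fistulaflow.lattice import (periodic_connectivity, stream,
                                     trt_collide, update_macroscopics)

    n = 4 * 4 * 4
    src = periodic_connectivity((4, 4, 4))
    F = np.tile([2e-6, 0.0, -1e-6], (n, 1))
    state = FluidState.at_rest(n)
    params = TRTParameters(tau_plus=0.8)
    n_steps = 50
    for _ in range(n_steps):
        update_macroscopics(state, force=F)
        trt_collide(state, params, force=F)
        stream(state, src)
    update_macroscopics(state, force=F)
    # after n collisions the accumulated momentum is n F; the macroscopic
    # velocity additionally carries the Guo half-force shift F/(2 rho)
    assert np.allclose(state.u[:, 0], (n_steps + 0.5) * 2e-6, rtol=1e-10)
    assert np.allclose(state.u[:, 2], -(n_steps + 0.5) * 1e-6, rtol=1e-10)


def test_dynamic_pressure_force_direction_and_antisymmetry(small_cylinder_domain):
    patch = small_cylinder_domain.opening("outlet")
    f1 = dynamic_pressure_force(patch, v_target_lat=0.02, v_current_lat=0.01)
    assert f1.force_lat @ patch.unit_normal > 0
    f2 = dynamic_pressure_force(patch, v_target_lat=-0.02, v_current_lat=-0.01)
    assert np.allclose(f2.force_lat, -f1.force_lat)
    f0 = dynamic_pressure_force(patch, v_target_lat=0.015, v_current_lat=0.015)
    assert np.allclose(f0.force_lat, 0.0)


# --------------------------------------------------------------------------
# junction symmetry
# --------------------------------------------------------------------------

def test_symmetric_y_splits_flow_equally():
    units = UnitSystem(dx=2e-4, dt=5e-4)
    domain = voxelize_vessels(yjunction_tree(), units.dx)
    instance = Instance(
        domain, units,
        inlets=[InletAssignment(patch_id="inlet", mode="waveform",
                                waveform=InletWaveform.steady(0.02, warmup_duration=0.05),
                                profile_radius=1.0e-3)],
        outlets=[OutletAssignment(patch_id="outlet_left"),
                 OutletAssignment(patch_id="outlet_right")])
    records = run_single(instance, 3000, cadence=500,
                         probe_openings=["inlet", "outlet_left", "outlet_right"])
    ql = records["outlet_left"].flows[-1]
    qr = records["outlet_right"].flows[-1]
    assert ql > 0 and qr > 0
    assert ql == pytest.approx(qr, rel=0.01)
    # in/out balance holds on the reference-density mass flow (volumetric
    # flux additionally carries the pseudo-compressible density gradient)
    q_in = -records["inlet"].ref_flows[-1]
    q_out = records["outlet_left"].ref_flows[-1] + records["outlet_right"].ref_flows[-1]
    assert q_out == pytest.approx(q_in, rel=0.01)


def test_global_mass_drift_with_static_boundaries(small_cylinder_domain):
    """Static boundaries, no forcing: global mass drifts < 1e-6 relative
    over 1e4 steps on the cylinder fixture."""
    units = UnitSystem(dx=2e-4, dt=1e-3)
    instance = Instance(
        small_cylinder_domain, units,
        inlets=[InletAssignment(patch_id="inlet", mode="waveform",
                                waveform=InletWaveform.steady(0.0, warmup_duration=0.0))],
        outlets=[OutletAssignment(patch_id="outlet", pressure_pa=0.0)])
    m0 = instance.state.f.sum()
    for s in range(1, 10_001):
        instance.step_once(s * units.dt)
    assert abs(instance.state.f.sum() - m0) / m0 < 1e-6


def test_inlet_tracks_waveform_over_one_period(small_cylinder_domain):
    """Time-averaged measured inlet flow equals the waveform mean times the
    patch area within 1% over one period (after the warm-up ramp)."""
    from fistulaflow.boundaries import brachial_waveform
    from fistulaflow.observables import measure_plane_flow, probe_from_opening
    from fistulaflow.lattice import update_macroscopics

    units = UnitSystem(dx=2e-4, dt=2e-4)
    wave = brachial_waveform(peak=0.06, mean=0.015, period=0.08,
                             warmup_duration=0.04)
    instance = Instance(
        small_cylinder_domain, units,
        inlets=[InletAssignment(patch_id="inlet", mode="waveform", waveform=wave)],
        outlets=[OutletAssignment(patch_id="outlet", pressure_pa=0.0)])
    probe = probe_from_opening(instance.domain, "inlet")
    warm_steps = int(round(wave.warmup_duration / units.dt))
    period_steps = int(round(wave.period / units.dt))
    for s in range(1, warm_steps + 1):
        instance.step_once(s * units.dt)
    flows = []
    for s in range(warm_steps + 1, warm_steps + period_steps + 1):
        instance.step_once(s * units.dt)
        update_macroscopics(instance.state, force=instance.force_lat)
        flows.append(-measure_plane_flow(instance.state, probe, units))
    area = instance.domain.opening("inlet").area
    assert np.mean(flows) == pytest.approx(wave.mean() * area, rel=0.01)
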