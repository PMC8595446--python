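import numpy as np
import pytest

from fistulaflow.coupling import (BedOpening, CapillaryBed, CouplingSchedule,
                                  FistulaPairing, bed_flow_update,
                                  bed_pressure_drop, couple_exchange,
                                  distribute_flow, fistula_exchange,
                                  flow_weighted_velocity)


def make_bed(R=1e9, C_bar=0.0, **kw):
    return CapillaryBed(
        id="bed",
        arterial=[BedOpening(id="a0", area=2e-6), BedOpening(id="a1", area=2e-6)],
        venous=[BedOpening(id="v0", area=1e-6), BedOpening(id="v1", area=3e-6)],
        R=R, C_bar=C_bar, **kw)


# --------------------------------------------------------------------------
# flow-weighted velocity (the aggregation step)
# --------------------------------------------------------------------------

def test_single_opening_returns_its_velocity():
    assert flow_weighted_velocity([3e-6], [0.25]) == pytest.approx(0.25)


def test_flow_weighted_velocity_hand_example():
    v_d = flow_weighted_velocity([1.0, 3.0], [0.2, 0.4])
    assert v_d == pytest.approx((0.04 + 0.48) / (0.2 + 1.2), rel=1e-12)


def test_constant_velocity_is_fixed_point(rng):
    areas = rng.uniform(1e-7, 1e-5, 6)
    assert flow_weighted_velocity(areas, np.full(6, 0.13)) == pytest.approx(0.13)


def test_degenerate_counterflow_returns_zero(caplog):
    with caplog.at_level("WARNING"):
        v = flow_weighted_velocity([1.0, 1.0], [0.3, -0.3])
    assert v == 0.0
    assert "degenerate" in caplog.text


def test_printed_form_is_plain_sum():
    assert flow_weighted_velocity([1.0, 3.0], [0.2, 0.4],
                                  form="plain_sum") == pytest.approx(0.6)


# --------------------------------------------------------------------------
# RC bed
# --------------------------------------------------------------------------

def test_pressure_drop_is_resistive():
    bed = make_bed(R=1e9)
    bed.Q_B = 1e-7
    assert bed_pressure_drop(bed) == pytest.approx(100.0)
    bed.Q_B = 0.0
    assert bed_pressure_drop(bed) == 0.0
    bed2 = make_bed(R=2e9)
    bed2.Q_B = 1e-7
    assert bed_pressure_drop(bed2) == pytest.approx(2 * 100.0)


def test_steady_flow_passes_through_unchanged():
    bed = make_bed(R=1e9, C_bar=1e-9)
    bed.Q_B = 2e-7
    assert bed_flow_update(bed, 2e-7, dt_couple=0.01) == pytest.approx(2e-7)


def test_zero_capacitance_is_pure_resistor(rng):
    bed = make_bed(C_bar=0.0)
    for q in rng.uniform(-1e-6, 1e-6, 10):
        assert bed_flow_update(bed, q, dt_couple=0.003) == pytest.approx(q)


def test_flow_update_hand_example():
    # Q_in = 2, Cbar R = 1 s, Q_B rising 0.5 -> 1.0 over 0.1 s => Q_out = 4.5
    bed = CapillaryBed(id="b", arterial=[BedOpening(id="a", area=1.0)],
                       venous=[BedOpening(id="v", area=1.0)], R=1.0, C_bar=1.0)
    bed.Q_B = 0.5
    assert bed_flow_update(bed, 2.0, dt_couple=0.1, Q_B=1.0) == pytest.approx(4.5)


def test_flow_update_rejects_bad_interval():
    with pytest.raises(ValueError):
        bed_flow_update(make_bed(), 1e-7, dt_couple=0.0)


def test_discrete_update_matches_fine_reference():
    """Backward-difference bed update converges to the continuous relation
    Q_out = Q_in + 1/2 Cbar R dQ_in/dt; a 1000x finer stepping serves as the
    reference."""
    CR = 0.1
    omega = 2 * np.pi
    dt_c = 1e-4

    def run(dt):
        bed = CapillaryBed(id="b", arterial=[BedOpening(id="a", area=1.0)],
                           venous=[BedOpening(id="v", area=1.0)],
                           R=1.0, C_bar=CR)
        t, out = 0.0, {}
        n_total = int(round(0.05 / dt))
        for k in range(1, n_total + 1):
            t = k * dt
            q = bed_flow_update(bed, np.sin(omega * t), dt)
            out[round(t, 10)] = q
        return out

    coarse = run(dt_c)
    fine = run(dt_c / 1000.0)
    ts = sorted(set(coarse) & set(fine))[5:]
    assert len(ts) > 100
    err = max(abs(coarse[t] - fine[t]) for t in ts)
    scale = max(abs(fine[t]) for t in ts)
    assert err / scale < 1e-3


def test_eq_consistency_along_trajectory(rng):
    """Q_A - Q_V + 1/2 Cbar R dQ_B/dt = 0 holds identically at updates."""
    bed = make_bed(R=2e8, C_bar=5e-10)
    dt = 0.0015
    for q_a in rng.uniform(0, 1e-6, 50):
        q_v = bed_flow_update(bed, q_a, dt)
        dqdt = (bed.Q_B - bed.Q_B_prev) / dt
        assert q_a - q_v + 0.5 * bed.C_bar * bed.R * dqdt == pytest.approx(0.0, abs=1e-20)


# --------------------------------------------------------------------------
# distribution
# --------------------------------------------------------------------------

def test_distribute_single_opening():
    v = distribute_flow(1e-6, [BedOpening(id="x", area=4e-6)])
    assert v["x"] == pytest.approx(0.25)


def test_distribute_area_proportional_gives_equal_velocities():
    targets = distribute_flow(1e-6, [BedOpening(id="a", area=1e-6),
                                     BedOpening(id="b", area=3e-6)])
    assert targets["a"] == pytest.approx(0.25)
    assert targets["b"] == pytest.approx(0.25)


def test_distribute_conserves_total(rng):
    openings = [BedOpening(id=str(i), area=a, coefficient=c)
                for i, (a, c) in enumerate(zip(rng.uniform(1e-7, 1e-5, 8),
                                               rng.uniform(0.2, 3.0, 8)))]
    Q = 3.7e-7
    targets = distribute_flow(Q, openings)
    assert sum(targets[o.id] * o.area for o in openings) == pytest.approx(Q, rel=1e-14)


def test_distribute_zero_flow_and_zero_weights():
    openings = [BedOpening(id="a", area=1e-6)]
    assert distribute_flow(0.0, openings)["a"] == 0.0
    with pytest.raises(ValueError):
        distribute_flow(1e-6, [BedOpening(id="a", area=1e-6, coefficient=0.0)])


# --------------------------------------------------------------------------
# exchange orchestration
# --------------------------------------------------------------------------

def test_schedule_fires_only_at_interval():
    s = CouplingSchedule(interval=500)
    fired = [step for step in range(0, 2001) if s.due(step)]
    assert fired == [500, 1000, 1500, 2000]


def test_direction_alternates_starting_artery_to_vein():
    s = CouplingSchedule(interval=10)
    seen = []
    for _ in range(4):
        seen.append(s.direction)
        s.flip()
    assert seen == ["artery_to_vein", "vein_to_artery"] * 2


def test_zero_flow_exchange_flips_direction_with_zero_targets():
    bed = make_bed()
    s = CouplingSchedule(interval=10)
    res = couple_exchange(bed, s, {"a0": 0.0, "a1": 0.0},
                          {"v0": 0.0, "v1": 0.0}, dt_couple=0.003)
    assert all(v == 0.0 for v in res.venous_inlet_targets.values())
    assert s.direction == "vein_to_artery"
    res2 = couple_exchange(bed, s, {"a0": 0.0, "a1": 0.0},
                           {"v0": 0.0, "v1": 0.0}, dt_couple=0.003)
    assert res2.arterial_outlet_targets.keys() == {"a0", "a1"}
    assert s.direction == "artery_to_vein"


def test_exchange_missing_opening_is_configuration_error():
    with pytest.raises(KeyError):
        couple_exchange(make_bed(), CouplingSchedule(interval=10),
                        {"a0": 0.1}, {"v0": 0.0, "v1": 0.0}, dt_couple=0.003)


def test_artery_to_vein_exchange_conserves_flow():
    bed = make_bed(C_bar=0.0)
    s = CouplingSchedule(interval=10)
    res = couple_exchange(bed, s, {"a0": 0.1, "a1": 0.2},
                          {"v0": 0.0, "v1": 0.0}, dt_couple=0.003)
    q_in = flow_weighted_velocity([2e-6, 2e-6], [0.1, 0.2]) * 4e-6
    q_out = sum(res.venous_inlet_targets[o.id] * o.area for o in bed.venous)
    assert q_out == pytest.approx(q_in, rel=1e-12)


# --------------------------------------------------------------------------
# fistula exchange
# --------------------------------------------------------------------------

def test_fistula_copies_velocity_for_equal_areas():
    pairing = FistulaPairing(pairs=[("art", "ven", 1.0)])
    t = fistula_exchange({"art": 0.21}, pairing)
    assert t["ven"] == pytest.approx(0.21)


def test_fistula_conserves_flow_across_dilated_junction():
    pairing = FistulaPairing(pairs=[("art", "ven", 1.0)])
    t = fistula_exchange({"art": 0.2}, pairing,
                         areas={"art": 1e-6, "ven": 2e-6}, conserve_flow=True)
    assert t["ven"] == pytest.approx(0.1)


def test_fistula_zero_flow_gives_zero_target():
    pairing = FistulaPairing(pairs=[("art", "ven", 0.8)])
    assert fistula_exchange({"art": 0.0}, pairing)["ven"] == 0.0


def test_fistula_pairing_must_be_one_to_one():
    with pytest.raises(ValueError):
        FistulaPairing(pairs=[("a", "v", 1.0), ("a", "w", 1.0)])


def test_coupling_map_yaml_round_trip(tmp_path):
    from fistulaflow.coupling import coupling_map_from_yaml, coupling_map_to_yaml

    beds = [make_bed(R=2e9, C_bar=1e-10)]
    pairing = FistulaPairing(pairs=[("anastomosis_art", "anastomosis_ven", 1.4)])
    path = tmp_path / "map.yaml"
    coupling_map_to_yaml(beds, pairing, path)
    beds2, pairing2 = coupling_map_from_yaml(path)
    assert beds2[0].R == 2e9 and beds2[0].C_bar == 1e-10
    assert [o.id for o in beds2[0].venous] == ["v0", "v1"]
    assert pairing2.pairs == pairing.pairs


def test_coupling_map_yaml_rejects_invalid(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text(
        "beds:\n- id: b\n  R_pa_s_per_m3: -1.0\n"
        "  arterial: [{id: a, area_m2: 1e-6}]\n"
        "  venous: [{id: v, area_m2: 1e-6}]\n")
    from fistulaflow.coupling import coupling_map_from_yaml
    with pytest.raises(ValueError):
        coupling_map_from_yaml(path)
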